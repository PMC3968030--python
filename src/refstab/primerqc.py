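"""Primer/amplicon design checks for qPCR assays.

Evaluates each assay against the design rules used for the reference-gene
panel: primer length 24-25 nt, amplicon 100-200 bp, GC content 50-60%,
annealing temperature 60+-1 degC with <0.5 degC difference between the two
primers, hairpin score <= 6 and self/pair dimer score <= 4.

Melting temperatures come from the nearest-neighbor thermodynamic model
(SantaLucia parameters, via biopython); they approximate, and are not
asserted equal to, the temperatures a design tool prints.  The hairpin and
dimer "scores" are a documented integer surrogate: the length of the
longest perfectly complementary antiparallel run (with a minimum loop of 3
bases for hairpins), on the scale of the Primer3-style parameters the
thresholds were written for.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .datamodel import ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
DNA_ALPHABET = set("ACGT")


def _check_seq(seq: str, what: str) -> str:
    s = seq.strip().upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValidationError(f"{what} contains non-ACGT character(s): {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    s = _check_seq(seq, "sequence")
    return 100.0 * sum(c in "GC" for c in s) / len(s)


def compute_tm(seq: str, salt_mm: float = 50.0, oligo_nm: float = 500.0) -> float:
    """Nearest-neighbor melting temperature in Celsius.

    Defaults: 50 mM monovalent salt, 500 nM oligo (in excess over
    template).
    """
    s = _check_seq(seq, "primer")
    if len(s) < 8:
        raise ValidationError("Tm needs a sequence of at least 8 nt")
    return float(MeltingTemp.Tm_NN(s, Na=salt_mm, dnac1=oligo_nm, dnac2=0,
                                   selfcomp=False))


def _longest_antiparallel_run(s1: str, s2: str) -> int:
    """Longest perfectly complementary antiparallel duplex between s1 and s2.

    Equivalent to the longest common substring of s1 and the reverse
    complement of s2.
    """
    t = reverse_complement(s2)
    n, m = len(s1), len(t)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if s1[i - 1] == t[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def hairpin_score(seq: str, min_loop: int = 3) -> int:
    """Longest intra-strand antiparallel complementary run with a loop >= 3.

    A stem of length k folds s[i:i+k] back onto s[j:j+k] (reverse
    complement) with an unpaired loop of j - (i + k) bases in between.
    Brute force over all (i, j, k); trivially fast for primer-length
    sequences.
    """
    s = _check_seq(seq, "primer")
    return _hairpin_scan(s, min_loop)


def _hairpin_scan(s: str, min_loop: int) -> int:
    n = len(s)
    best = 0
    for i in range(n):
        for j in range(i + 1, n):
            kmax = min(n - j, j - i - min_loop)
            for k in range(best + 1, kmax + 1):
                if j - (i + k) < min_loop:
                    break
                if s[j:j + k] == reverse_complement(s[i:i + k]):
                    best = k
    return best


def dimer_scores(fwd: str, rev: str) -> tuple[int, int, int]:
    """(hairpin, self_dimer, pair_dimer) integer scores for a primer pair.

    hairpin is the worse of the two primers' hairpin scores; self_dimer the
    worse self-annealing run; pair_dimer the fwd/rev cross-annealing run.
    """
    f = _check_seq(fwd, "forward primer")
    r = _check_seq(rev, "reverse primer")
    hp = max(_hairpin_scan(f, 3), _hairpin_scan(r, 3))
    sd = max(_longest_antiparallel_run(f, f), _longest_antiparallel_run(r, r))
    pdim = _longest_antiparallel_run(f, r)
    return hp, sd, pdim


@dataclass
class DesignRules:
    """Assay design thresholds (defaults: the panel's design criteria)."""

    primer_len: tuple[int, int] = (24, 25)
    amplicon_len: tuple[int, int] = (100, 200)
    gc_percent: tuple[float, float] = (50.0, 60.0)
    tm_celsius: tuple[float, float] = (59.0, 61.0)
    max_tm_diff: float = 0.5
    max_hairpin: int = 6
    max_dimer: int = 4


@dataclass
class PrimerAssay:
    """A qPCR primer pair, optionally with its amplicon sequence or length."""

    assay_id: str
    fwd_seq: str
    rev_seq: str
    amplicon_seq: str | None = None
    amplicon_len: int | None = None

    def __post_init__(self) -> None:
        self.fwd_seq = _check_seq(self.fwd_seq, f"{self.assay_id} forward primer")
        self.rev_seq = _check_seq(self.rev_seq, f"{self.assay_id} reverse primer")
        if self.amplicon_seq is not None:
            self.amplicon_seq = _check_seq(self.amplicon_seq,
                                           f"{self.assay_id} amplicon")
            if self.amplicon_len is None:
                self.amplicon_len = len(self.amplicon_seq)


def check_assay(assay: PrimerAssay, rules: DesignRules | None = None
                ) -> pd.DataFrame:
    """Evaluate one assay; returns a (criterion, value, threshold, passed) table."""
    rules = rules or DesignRules()
    tm_f = compute_tm(assay.fwd_seq)
    tm_r = compute_tm(assay.rev_seq)
    hp, sd, pdim = dimer_scores(assay.fwd_seq, assay.rev_seq)
    lo, hi = rules.primer_len
    rows = [
        ("fwd_length", len(assay.fwd_seq), f"[{lo},{hi}]",
         lo <= len(assay.fwd_seq) <= hi),
        ("rev_length", len(assay.rev_seq), f"[{lo},{hi}]",
         lo <= len(assay.rev_seq) <= hi),
        ("fwd_gc_percent", round(gc_percent(assay.fwd_seq), 2),
         f"[{rules.gc_percent[0]},{rules.gc_percent[1]}]",
         rules.gc_percent[0] <= gc_percent(assay.fwd_seq) <= rules.gc_percent[1]),
        ("rev_gc_percent", round(gc_percent(assay.rev_seq), 2),
         f"[{rules.gc_percent[0]},{rules.gc_percent[1]}]",
         rules.gc_percent[0] <= gc_percent(assay.rev_seq) <= rules.gc_percent[1]),
        ("fwd_tm", round(tm_f, 2),
         f"[{rules.tm_celsius[0]},{rules.tm_celsius[1]}]",
         rules.tm_celsius[0] <= tm_f <= rules.tm_celsius[1]),
        ("rev_tm", round(tm_r, 2),
         f"[{rules.tm_celsius[0]},{rules.tm_celsius[1]}]",
         rules.tm_celsius[0] <= tm_r <= rules.tm_celsius[1]),
        ("tm_diff", round(abs(tm_f - tm_r), 3), f"<{rules.max_tm_diff}",
         abs(tm_f - tm_r) < rules.max_tm_diff),
        ("hairpin", hp, f"<={rules.max_hairpin}", hp <= rules.max_hairpin),
        ("self_dimer", sd, f"<={rules.max_dimer}", sd <= rules.max_dimer),
        ("pair_dimer", pdim, f"<={rules.max_dimer}", pdim <= rules.max_dimer),
    ]
    if assay.amplicon_len is not None:
        alo, ahi = rules.amplicon_len
        rows.insert(2, ("amplicon_length", assay.amplicon_len, f"[{alo},{ahi}]",
                        alo <= assay.amplicon_len <= ahi))
    out = pd.DataFrame(rows, columns=["criterion", "value", "threshold", "passed"])
    out.insert(0, "assay_id", assay.assay_id)
    return out


def check_panel(assays: list[PrimerAssay], rules: DesignRules | None = None
                ) -> pd.DataFrame:
    return pd.concat([check_assay(a, rules) for a in assays], ignore_index=True)
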