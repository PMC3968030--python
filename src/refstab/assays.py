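"""The published *Silene latifolia* qPCR assay panel (fixture data).

Primer pairs, amplicon lengths, annealing temperatures and LinReg-estimated
amplification efficiencies for the 21 novel candidate reference-gene assays
(designed from RNA-seq contigs, GenBank GARX01000000), the six traditional
reference-gene assays (actin, tubulin, GAPDH, EF1, ubiquitin, UBCE; designed
earlier from ESTs under looser rules), and the printed per-assay values used
as inputs elsewhere in the pipeline.

Sequences are stored exactly as printed in the source table.  Three reverse
primers (SL_METL1, SL_COQ3, SL_AKT6) print at 23 nt although all novel
assays were designed at 24-25 nt; these entries are flagged
``truncated_in_source`` because the transcription of the table, not the
design, is short.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .primerqc import PrimerAssay


@dataclass(frozen=True)
class AssayRecord:
    assay_id: str
    fwd: str
    rev: str
    amplicon_len: int
    tm_celsius: float
    efficiency: float
    traditional: bool = False
    truncated_in_source: bool = False


PANEL: tuple[AssayRecord, ...] = (
    AssayRecord("SL_REF1", "TCCTCGGAAGGTTCAAGGGTGTCTT", "TTGGTATCGGTTGGCGGGAGTTTTC", 102, 59.4, 1.89),
    AssayRecord("SL_REF2", "GCAGTGGTTGTAGTCCGGCATTAGT", "GAGTGTTGCGGTGGAGAGATTGCTT", 124, 59.3, 1.89),
    AssayRecord("SL_BXL4", "TTTGCTCCTTGCATCGCGGTTTGT", "ACACCCTTTGCGTTATGTGGGAGGT", 143, 60.4, 1.88),
    AssayRecord("SL_EDL16", "GGGGCCAATTTCACTTGATGCTGGA", "TAATCCGCCTCGGATACTGGTTGGT", 118, 59.5, 1.85),
    AssayRecord("SL_METL1", "TCCGGTGGTTGGGTTCCTCCTAAAA", "GCCGCATGCCAGTGTCAACAAAA", 116, 59.5, 1.77,
                truncated_in_source=True),
    AssayRecord("SL_REF3", "CGCCAGGCAGAGGTGTTAAACCAGA", "TAGCAGCAGTTACGAGCCCCAACA", 145, 60.5, 1.77),
    AssayRecord("SL_REF4", "AAAGCGACGATCTTAGGGCGGTTTG", "TCCCCATGTTTGGAGAGGAACTGCT", 153, 59.7, 1.87),
    AssayRecord("SL_REF5", "TTCCAGGCCCTTAGTGTTAGGGGTT", "AGGGGGAGCTAGCTAAGTGACTTCC", 176, 59.0, 1.89),
    AssayRecord("SL_PREP1", "CGCCTCCGCCTTATCTTCGTCATTT", "CTCAACCACCTGCTCGGACACTTTT", 178, 59.4, 1.89),
    AssayRecord("SL_PIP5K8", "ACTCCAACGGCGACCCAAAAGAAA", "TAGACGAATCTGCGCTCGTCCTCTT", 187, 59.5, 1.89),
    AssayRecord("SL_COQ3", "ACGGTCTACGCTTTGCCATCACTTC", "AACACCTGTCACCGTAGCTCCCA", 142, 59.6, 1.86,
                truncated_in_source=True),
    AssayRecord("SL_BL52", "TGGTTTTGTCCCCACCGAAACGAA", "TATCCCCATCTGGTTGAGCGGTTCT", 124, 59.2, 1.84),
    AssayRecord("SL_RPM1", "AGAGTGTATGTCTGCCAACTGCCCT", "CGGGGAAAGCGAGAATTTGGAGGTT", 183, 59.6, 1.88),
    AssayRecord("SL_PDXK", "TCATCAATGGCGCAACCTCCGATT", "ACCGGGTCAACATCAAAACCAAGCA", 152, 59.4, 1.82),
    AssayRecord("SL_ASPL1", "ACGCCGGCTTTGTTGTTCATCAGT", "ATGCAATTCGGGTGGTCTCGTTCAG", 108, 59.7, 1.90),
    AssayRecord("SL_REF6", "AACTCCCTGTTCTCACCCCATTCCT", "AATCTTCAGTTGCGGAGGGGCTTAC", 100, 59.1, 1.91),
    AssayRecord("SL_BLUS1", "CCACCACTATGGGATCGCGTGAAA", "TTCCAGGCACTGACACCTCTCTTGT", 131, 59.3, 1.81),
    AssayRecord("SL_STR1", "ACCCAGTGCAAGAACACAAGCAGT", "ACGGAAGGGCATTAGGAGTGGTCAT", 193, 59.4, 1.84),
    AssayRecord("SL_AKT6", "TGACTCGGGATCAGCCAGTTCACA", "TTCATCATGCAGCCCGAGGTGAG", 122, 59.3, 1.84,
                truncated_in_source=True),
    AssayRecord("SL_REF7", "AGTTGGTACTTGGCGTTTGAGGGAC", "AGGCTCCCTAGGAAACAGTCGGAAA", 185, 59.1, 1.83),
    AssayRecord("SL_REF8", "GCTTGTGGAAGCAGGGGATCTTTGT", "AGGGCCAGTTTCCGCATGATTTGT", 174, 59.4, 1.91),
    AssayRecord("SL_TUB", "CTGGGAAATACGCAGGTGAT", "ATTCCCAGCACCAGATTGAC", 200, 59.9, 1.90, traditional=True),
    AssayRecord("SL_ACTIN", "CTGGTTTCGCTGGAGATGAT", "GGGTTCAATGGTGCTTCTGT", 280, 60.1, 1.89, traditional=True),
    AssayRecord("SL_UBCE", "TTCATTGCTTGCCACTTCTG", "CAAATGCGAGCTGAAAAACA", 201, 60.0, 1.86, traditional=True),
    AssayRecord("SL_EF1", "GGCCACTTTCTGCTCTGGTA", "GGTCTTCACGGACACTGGTT", 182, 59.8, 1.84, traditional=True),
    AssayRecord("SL_GAPDH", "GCGAGACTGGAGCTGATTTC", "ACAACTGGCATTGGACACAA", 194, 60.1, 1.87, traditional=True),
    AssayRecord("SL_UBQ", "AATTTTCGCCTTCCTCATCC", "GCTTGCCAGCGAAAATAAGT", 396, 60.0, 1.80, traditional=True),
)


def panel_frame() -> pd.DataFrame:
    """The panel as a DataFrame indexed by assay id."""
    return pd.DataFrame([vars(a) for a in PANEL]).set_index("assay_id")


def panel_efficiencies() -> pd.Series:
    """Per-assay amplification efficiencies, ready for a CtTable."""
    return pd.Series({a.assay_id: a.efficiency for a in PANEL}, name="efficiency")


def panel_assays(traditional: bool | None = None) -> list[PrimerAssay]:
    """PrimerAssay objects, optionally restricted to (non-)traditional assays."""
    out = []
    for a in PANEL:
        if traditional is not None and a.traditional is not traditional:
            continue
        out.append(PrimerAssay(assay_id=a.assay_id, fwd_seq=a.fwd, rev_seq=a.rev,
                               amplicon_len=a.amplicon_len))
    return out
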