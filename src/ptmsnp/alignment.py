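"""Window alignment primitives.

Two routes locate an nsSNP relative to a PTM site when the two source
databases disagree on the protein sequence:

1. ``slide_candidates`` — the 15-mer SNP window is slid across the 15-mer
   PTM-site window one residue at a time; exact residue identities are
   counted at every superposition.  This is the workhorse.
2. ``needleman_wunsch``/``fallback_offset`` — an affine-gap global pairwise
   alignment (EMBOSS-Needle-style defaults: BLOSUM62, gap open 10.0, gap
   extend 0.5, free end gaps) resolves the rare ambiguous cases caused by
   sequence repeats, preferably on the full protein sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import PAD, ProteinRecord, PtmSite, SnpRecord, WindowPeptide


@dataclass(frozen=True)
class OffsetCandidate:
    """One superposition of the SNP window on the PTM window.

    ``offset`` is the signed position of the SNP relative to the PTM site
    (negative = N-terminal); ``overlap`` counts column pairs where both
    windows carry real sequence; ``identities`` counts exact matches there.
    """

    offset: int
    overlap: int
    identities: int


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    def matrix_array(self):
        return _load_matrix(self.matrix)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    """Load a named substitution matrix, or one from an NCBI/EMBOSS-format
    matrix file if ``name`` is a path."""
    if Path(name).is_file():
        with open(name) as fh:
            return substitution_matrices.read(fh)
    return substitution_matrices.load(name)


def slide_candidates(
    snp_window: WindowPeptide,
    ptm_window: WindowPeptide,
    min_overlap: int = 8,
    max_mismatch: int = 1,
) -> list[OffsetCandidate]:
    """Enumerate every superposition of the SNP window on the PTM window.

    For offset ``k`` the SNP window's center sits on PTM-window index
    ``center + k``.  Candidates with ``overlap >= min_overlap`` and
    ``overlap - identities <= max_mismatch`` are returned sorted by
    identities descending, then \\|k\\| ascending, then k ascending.

    Identity counting is exact residue equality; ``X`` never matches and the
    pad character contributes to neither overlap nor identities.
    """
    if snp_window.flank != ptm_window.flank:
        raise ValueError(
            f"flank mismatch: {snp_window.flank} vs {ptm_window.flank}"
        )
    flank = snp_window.flank
    width = 2 * flank + 1
    a, b = snp_window.residues, ptm_window.residues
    out: list[OffsetCandidate] = []
    for k in range(-flank, flank + 1):
        overlap = identities = 0
        for i in range(width):
            j = i + k
            if not 0 <= j < width:
                continue
            ra, rb = a[i], b[j]
            if ra == PAD or rb == PAD:
                continue
            overlap += 1
            if ra == rb and ra != "X":
                identities += 1
        if overlap >= min_overlap and overlap - identities <= max_mismatch:
            out.append(OffsetCandidate(k, overlap, identities))
    out.sort(key=lambda c: (-c.identities, abs(c.offset), c.offset))
    return out


def _map_to_matrix_alphabet(seq: str, alphabet: str) -> str:
    """Residues absent from the matrix are scored as the matrix's X row."""
    return "".join(c if c in alphabet else "X" for c in seq)


def needleman_wunsch(a: str, b: str, params: AlignParams = AlignParams()) -> AlignmentResult:
    """Optimal global pairwise alignment under the affine gap model.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; with
    ``penalize_end_gaps=False`` (the default, as in EMBOSS Needle) leading
    and trailing gap runs are free.
    """
    if not a or not b:
        raise ValueError("needleman_wunsch requires non-empty sequences")
    matrix = params.matrix_array()
    alphabet = str(matrix.alphabet)
    a_m = _map_to_matrix_alphabet(a, alphabet)
    b_m = _map_to_matrix_alphabet(b, alphabet)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if not params.penalize_end_gaps:
        if hasattr(aligner, "open_end_gap_score"):
            aligner.open_end_gap_score = 0.0
            aligner.extend_end_gap_score = 0.0
        else:  # Biopython < 1.88 attribute names
            aligner.end_open_gap_score = 0.0
            aligner.end_extend_gap_score = 0.0
    aln = aligner.align(a_m, b_m)[0]
    aligned_a_m, aligned_b_m = str(aln[0]), str(aln[1])

    # restore the original residues (unknowns were mapped to X for scoring)
    def restore(aligned: str, original: str) -> str:
        it = iter(original)
        return "".join(next(it) if c != PAD else PAD for c in aligned)

    return AlignmentResult(restore(aligned_a_m, a), restore(aligned_b_m, b), float(aln.score))


def _window_seq_and_pos(window: WindowPeptide) -> tuple[str, int]:
    """De-padded window plus the 1-based position of its center within it."""
    return window.depadded, window.center_index - window.n_lead_pads + 1


def fallback_offset(
    snp: SnpRecord,
    ptm: PtmSite,
    snp_protein: ProteinRecord | None = None,
    ptm_protein: ProteinRecord | None = None,
    params: AlignParams = AlignParams(),
    flank: int = 7,
) -> int | None:
    """Resolve a repeat-ambiguous SNP/PTM pairing by global alignment.

    Full protein sequences are aligned when both are supplied, otherwise the
    de-padded windows.  The offset is the signed number of SNP-side residues
    between the alignment column of the PTM position and that of the SNP
    position.  Returns ``None`` when either focal residue sits opposite a
    gap or the offset falls outside ±flank.
    """
    if snp_protein is not None and ptm_protein is not None:
        a, pa = snp_protein.sequence, snp.position
        b, pb = ptm_protein.sequence, ptm.position
    else:
        if snp.snp_window is None or ptm.ptm_window is None:
            raise ValueError("fallback_offset needs either both proteins or both windows")
        a, pa = _window_seq_and_pos(snp.snp_window)
        b, pb = _window_seq_and_pos(ptm.ptm_window)

    result = needleman_wunsch(a, b, params)
    col_a = col_b = None
    na = nb = 0
    for col, (ca, cb) in enumerate(zip(result.aligned_a, result.aligned_b)):
        if ca != PAD:
            na += 1
            if na == pa:
                col_a = col
        if cb != PAD:
            nb += 1
            if nb == pb:
                col_b = col
    if col_a is None or col_b is None:
        return None
    if result.aligned_b[col_a] == PAD or result.aligned_a[col_b] == PAD:
        return None
    if col_a >= col_b:
        offset = sum(
            1 for c in range(col_b + 1, col_a + 1) if result.aligned_a[c] != PAD
        )
    else:
        offset = -sum(
            1 for c in range(col_a, col_b) if result.aligned_a[c] != PAD
        )
    if abs(offset) > flank:
        return None
    return offset
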