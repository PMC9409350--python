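"""Global pairwise alignment and best-template selection.

The pipeline's first step: each query is globally aligned (Needleman–Wunsch
with affine gaps) against every template in the registry, and the template
with the highest percent identity is selected as the reference for locating
the tunnel floor residues.  Alignment is delegated to Biopython's
``PairwiseAligner``; identity is counted over both-non-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import ProteinSequence

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "TemplateMatch",
    "AlignmentError",
    "global_align",
    "percent_identity",
    "select_best_template",
]

GAP = "-"


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global alignment.

    Gap penalties are positive score units; a gap run of length L costs
    ``gap_open + (L - 1) * gap_extend``.  Defaults are the common protein
    settings (BLOSUM62, 11/1).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend > 0:
            raise AlignmentError("require gap_open >= gap_extend > 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of query against subject.

    ``query_row`` and ``subject_row`` are equal-length gapped strings;
    ``subject_columns[i]`` is the alignment column holding subject position
    ``i`` (0-based).
    """

    query_row: str
    subject_row: str
    score: float
    subject_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.subject_row):
            raise AlignmentError("alignment rows must have equal length")

    @property
    def identity(self) -> float:
        return percent_identity(self)


@dataclass(frozen=True)
class TemplateMatch:
    """Best-template selection outcome; retains all candidate identities."""

    template_id: str
    alignment: PairwiseAlignment
    identity: float
    all_identities: dict[str, float]


@lru_cache(maxsize=8)
def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    query: ProteinSequence | str,
    subject: ProteinSequence | str,
    params: AlignmentParams = AlignmentParams(),
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``subject``.

    Deterministic: of the co-optimal tracebacks, the aligner's first path is
    taken.  Raises :class:`AlignmentError` on empty input.
    """
    q = query.residues if isinstance(query, ProteinSequence) else str(query).upper()
    s = subject.residues if isinstance(subject, ProteinSequence) else str(subject).upper()
    if not q or not s:
        raise AlignmentError("cannot align empty sequences")
    aligner = _make_aligner(params)
    alignment = next(iter(aligner.align(q, s)))
    query_row, subject_row = str(alignment[0]), str(alignment[1])

    subject_columns: list[int] = []
    for col, ch in enumerate(subject_row):
        if ch != GAP:
            subject_columns.append(col)
    result = PairwiseAlignment(
        query_row=query_row,
        subject_row=subject_row,
        score=float(alignment.score),
        subject_columns=tuple(subject_columns),
    )
    # paranoia: rows must regenerate the inputs
    assert query_row.replace(GAP, "") == q and subject_row.replace(GAP, "") == s
    return result


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Fraction of identical pairs over both-non-gap columns, in [0, 1]."""
    both = 0
    same = 0
    for a, b in zip(alignment.query_row, alignment.subject_row):
        if a != GAP and b != GAP:
            both += 1
            if a == b:
                same += 1
    if both == 0:
        raise AlignmentError("alignment has no both-non-gap columns")
    return same / both


def select_best_template(
    query: ProteinSequence,
    registry: "TemplateRegistry",
    params: AlignmentParams = AlignmentParams(),
) -> TemplateMatch:
    """Align the query to every registry template and pick the one with
    maximal percent identity; ties go to the earlier template in registry
    order.  All identities are retained for reporting."""
    templates = list(registry)
    if not templates:
        raise AlignmentError("template registry is empty")
    best_id: str | None = None
    best_aln: PairwiseAlignment | None = None
    best_ident = -1.0
    all_idents: dict[str, float] = {}
    for tpl in templates:
        aln = global_align(query, tpl.sequence, params)
        ident = percent_identity(aln)
        all_idents[tpl.pdb_id] = ident
        if ident > best_ident:
            best_ident = ident
            best_id = tpl.pdb_id
            best_aln = aln
    assert best_id is not None and best_aln is not None
    return TemplateMatch(
        template_id=best_id,
        alignment=best_aln,
        identity=best_ident,
        all_identities=all_idents,
    )
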