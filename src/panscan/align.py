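"""Pairwise protein alignment under a single fixed scoring scheme.

Every identity number reported anywhere in this package comes through this
module, so the conventions are stated once here:

* scoring: BLOSUM62, gap open 10, gap extension 0.5;
* ``local`` mode is a Smith-Waterman alignment, ``semiglobal`` is a global
  alignment with cost-free terminal gaps (overhangs of either sequence are
  not penalized and not counted);
* percent identity = 100 x (identical aligned residue pairs) /
  (aligned columns including internal gaps, excluding terminal overhangs).
  This approximates the global-identity convention used by whole-protein
  ortholog clustering tools;
* coverage = percent of reference residues that appear inside the aligned
  core (the region between the first and last column where both sequences
  are present).

Alignments are deterministic: when several optimal alignments exist the
first traceback reported by :class:`Bio.Align.PairwiseAligner` is used,
which prefers the left-most placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise alignment of a query against a reference.

    ``column_map`` maps 0-based reference positions inside the aligned core
    to the query position carrying that column, or ``None`` where the
    reference residue is aligned to a gap.
    """

    score: float
    identity_pct: float
    coverage_pct: float
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    column_map: dict[int, int | None] = field(repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")


def _validate(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"{name} contains non-amino-acid characters: {sorted(bad)!r}"
        )
    if not seq:
        raise ValueError(f"{name} is empty")
    return seq


@lru_cache(maxsize=4)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    if mode == "local":
        aligner.mode = "local"
    elif mode == "semiglobal":
        aligner.mode = "global"
        aligner.end_gap_score = 0.0
    else:
        raise ValueError(f"unknown alignment mode: {mode!r}")
    return aligner


def score_pair(query: str, reference: str, mode: str = "local") -> float:
    """Optimal alignment score only (no traceback); the fast path for
    best-hit searches where identities are not needed."""
    query = _validate(query, "query")
    reference = _validate(reference, "reference")
    return float(_aligner(mode).score(query, reference))


def align_pair(query: str, reference: str, mode: str = "local") -> AlignmentResult:
    """Align ``query`` to ``reference`` and report identity, coverage and the
    reference-to-query column map.

    Parameters
    ----------
    query, reference:
        Amino-acid strings over the 20 standard residues plus ``X``.
    mode:
        ``"local"`` or ``"semiglobal"`` (see module docstring).
    """
    query = _validate(query, "query")
    reference = _validate(reference, "reference")
    aln = _aligner(mode).align(query, reference)[0]

    # indices: 2 x n_columns, row 0 = query, row 1 = reference; -1 marks a gap
    inds = aln.indices
    qrow, rrow = inds[0], inds[1]
    both = (qrow >= 0) & (rrow >= 0)
    if not both.any():  # pragma: no cover - cannot happen for non-empty inputs
        raise ValueError("alignment has no aligned columns")
    core_lo = int(np.argmax(both))
    core_hi = len(both) - int(np.argmax(both[::-1]))  # exclusive

    q_core = qrow[core_lo:core_hi]
    r_core = rrow[core_lo:core_hi]
    n_columns = core_hi - core_lo

    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    rarr = np.frombuffer(reference.encode(), dtype=np.uint8)
    paired = (q_core >= 0) & (r_core >= 0)
    n_ident = int(
        (qarr[q_core[paired]] == rarr[r_core[paired]]).sum()
    )

    identity_pct = 100.0 * n_ident / n_columns
    coverage_pct = 100.0 * int((r_core >= 0).sum()) / len(reference)

    q_pos = q_core[q_core >= 0]
    r_pos = r_core[r_core >= 0]
    query_span = (int(q_pos.min()), int(q_pos.max()) + 1)
    ref_span = (int(r_pos.min()), int(r_pos.max()) + 1)

    column_map: dict[int, int | None] = {}
    for q, r in zip(q_core.tolist(), r_core.tolist()):
        if r >= 0:
            column_map[r] = q if q >= 0 else None

    return AlignmentResult(
        score=float(aln.score),
        identity_pct=identity_pct,
        coverage_pct=coverage_pct,
        query_span=query_span,
        ref_span=ref_span,
        column_map=column_map,
    )
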