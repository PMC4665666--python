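"""Per-position homology descriptors from bit-score-filtered alignments.

Hits whose bit score falls below a fraction (default 40%) of the best score
for the query are discarded; the surviving subject residues are tallied into
a per-position count profile over the 20 amino acids.  From the profile come
four descriptors per position:

* E20 — Shannon entropy of the column over the 20 amino-acid types,
  ``s_k = -sum_j P_jk ln P_jk`` with ``P_jk = count_jk / N_k``;
* E6  — the same entropy after pooling the 20 types into six physicochemical
  classes (coarse-graining, so ``E6 <= E20`` always);
* FSHP — fraction of aligned residues that are strongly hydrophobic
  (V, L, I, F, Y, M, W);
* FSR — fraction of aligned residues that are small (G, A).

Gaps and non-standard subject letters are excluded from both the numerator
and the denominator of all four descriptors.  Entropies are in nats.

A chain with at least ``min_hits`` (default 10) subject sequences surviving
the filter has *optimum homology*: only there are the homology descriptors
considered reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    GAP,
    NON_OPTIMUM,
    OPTIMUM,
    SMALL_RESIDUES,
    STANDARD_AA,
    STRONGLY_HYDROPHOBIC,
    UNDEFINED_AA,
    ChainSequence,
    PairwiseHit,
    ParseError,
)

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass(frozen=True)
class AminoClassScheme:
    """A partition of the 20 amino acids into six disjoint, exhaustive classes."""

    name: str
    classes: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != 6:
            raise ValueError(
                f"scheme {self.name!r}: expected 6 classes, got "
                f"{len(self.classes)}"
            )
        union: set[str] = set()
        total = 0
        for cls in self.classes:
            union |= set(cls)
            total += len(cls)
        if union != set(STANDARD_AA) or total != 20:
            raise ValueError(
                f"scheme {self.name!r}: classes must partition the 20 "
                f"standard amino acids"
            )

    def class_index(self) -> np.ndarray:
        """Array mapping amino-acid index (alphabetical) to class index."""
        idx = np.empty(20, dtype=int)
        for ci, cls in enumerate(self.classes):
            for aa in cls:
                idx[_AA_INDEX[aa]] = ci
        return idx


#: Default six-class scheme: aliphatic/hydrophobic, aromatic, polar, basic,
#: acidic, conformationally special.  Configurable — substitute any
#: :class:`AminoClassScheme` to explore alternatives.
DEFAULT_SIX_CLASSES = AminoClassScheme(
    name="default6",
    classes=(
        frozenset("AVLIMC"),   # aliphatic / hydrophobic
        frozenset("FWYH"),     # aromatic
        frozenset("STNQ"),     # polar
        frozenset("KR"),       # basic
        frozenset("DE"),       # acidic
        frozenset("GP"),       # special (flexible / rigid backbone)
    ),
)


@dataclass
class AlignmentProfile:
    """Per-position counts of aligned (non-gap) subject residues.

    ``counts[k-1, j]`` is the number of retained subject sequences showing
    amino acid ``STANDARD_AA[j]`` aligned to query position ``k``.  ``N_k``
    (``n_aligned``) is the row sum.  ``n_hits`` is the number of subject
    sequences retained after bit-score filtering, regardless of coverage.
    """

    chain_id: str
    counts: np.ndarray
    n_hits: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 20:
            raise ValueError("counts must have shape (length, 20)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def n_aligned(self) -> np.ndarray:
        """``N_k`` for every position (1-based position k at index k-1)."""
        return self.counts.sum(axis=1)


def filter_hits(hits: list[PairwiseHit], fraction: float = 0.4) -> list[PairwiseHit]:
    """Keep hits with bit score >= ``fraction`` x the best score.

    The boundary is inclusive; order is preserved; an empty hit list returns
    an empty result.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not hits:
        return []
    cutoff = fraction * max(h.bit_score for h in hits)
    return [h for h in hits if h.bit_score >= cutoff]


def build_profile(query: ChainSequence, hits: list[PairwiseHit]) -> AlignmentProfile:
    """Tally filtered hits into a per-position count profile.

    Every non-gap query column of a hit maps to one query position; the
    paired subject letter increments that position's counts unless it is a
    gap or a non-standard letter.  A hit whose (ungapped) aligned query
    disagrees with the query sequence at its stated offset is an error;
    'X' on either side matches anything.
    """
    counts = np.zeros((len(query), 20), dtype=float)
    for hit in hits:
        if hit.query_start + hit.query_span - 1 > len(query):
            raise ParseError(
                f"hit {hit.query_id!r}/{hit.subject_id!r}: alignment runs "
                f"past the end of chain {query.chain_id!r} "
                f"(qstart={hit.query_start}, span={hit.query_span}, "
                f"length={len(query)})"
            )
        pos = hit.query_start
        for q_letter, s_letter in zip(hit.aligned_query, hit.aligned_subject):
            if q_letter == GAP:
                continue
            expected = query.residue(pos)
            if (
                q_letter != expected
                and q_letter != UNDEFINED_AA
                and expected != UNDEFINED_AA
            ):
                raise ParseError(
                    f"hit {hit.query_id!r}/{hit.subject_id!r}: aligned query "
                    f"letter {q_letter!r} at position {pos} disagrees with "
                    f"chain {query.chain_id!r} residue {expected!r}"
                )
            if s_letter != GAP and s_letter in _AA_INDEX:
                counts[pos - 1, _AA_INDEX[s_letter]] += 1
            pos += 1
    return AlignmentProfile(chain_id=query.chain_id, counts=counts, n_hits=len(hits))


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total < 1:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def entropy20(profile: AlignmentProfile, k: int) -> float:
    """20-type sequence entropy at 1-based position ``k`` (nats, in [0, ln 20]).

    Positions with no aligned subject residues yield NaN (missing) and are
    excluded downstream.
    """
    return _entropy_from_counts(profile.counts[k - 1])


def entropy6(
    profile: AlignmentProfile,
    k: int,
    scheme: AminoClassScheme = DEFAULT_SIX_CLASSES,
) -> float:
    """Six-class sequence entropy at position ``k`` (nats, in [0, ln 6])."""
    row = profile.counts[k - 1]
    class_counts = np.bincount(scheme.class_index(), weights=row, minlength=6)
    return _entropy_from_counts(class_counts)


def _fraction(profile: AlignmentProfile, k: int, members: frozenset) -> float:
    row = profile.counts[k - 1]
    total = row.sum()
    if total < 1:
        return float("nan")
    sel = sum(row[_AA_INDEX[aa]] for aa in members)
    return float(sel / total)


def fshp(profile: AlignmentProfile, k: int) -> float:
    """Fraction of aligned residues at ``k`` that are strongly hydrophobic."""
    return _fraction(profile, k, STRONGLY_HYDROPHOBIC)


def fsr(profile: AlignmentProfile, k: int) -> float:
    """Fraction of aligned residues at ``k`` that are small (G or A)."""
    return _fraction(profile, k, SMALL_RESIDUES)


def homology_status(profile: AlignmentProfile, min_hits: int = 10) -> str:
    """'optimum' iff at least ``min_hits`` subject sequences survived the filter."""
    return OPTIMUM if profile.n_hits >= min_hits else NON_OPTIMUM


def profile_descriptors(
    profile: AlignmentProfile,
    scheme: AminoClassScheme = DEFAULT_SIX_CLASSES,
    min_hits: int = 10,
):
    """All four homology descriptors for every position, vectorized.

    Returns ``(e20, e6, fshp, fsr, n_aligned, status)`` where the first four
    are float arrays of length L (NaN where ``N_k = 0``) and ``status`` is
    the chain-level homology flag.
    """
    counts = profile.counts
    n_k = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p20 = counts / n_k[:, None]
        e20_arr = -np.nansum(np.where(p20 > 0, p20 * np.log(p20), 0.0), axis=1)
        class_idx = scheme.class_index()
        c6 = np.zeros((counts.shape[0], 6))
        for j in range(20):
            c6[:, class_idx[j]] += counts[:, j]
        p6 = c6 / n_k[:, None]
        e6_arr = -np.nansum(np.where(p6 > 0, p6 * np.log(p6), 0.0), axis=1)
        hyd = [_AA_INDEX[aa] for aa in STRONGLY_HYDROPHOBIC]
        sml = [_AA_INDEX[aa] for aa in SMALL_RESIDUES]
        fshp_arr = counts[:, hyd].sum(axis=1) / n_k
        fsr_arr = counts[:, sml].sum(axis=1) / n_k
    empty = n_k < 1
    for arr in (e20_arr, e6_arr, fshp_arr, fsr_arr):
        arr[empty] = np.nan
    return e20_arr, e6_arr, fshp_arr, fsr_arr, n_k, homology_status(profile, min_hits)
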