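"""Query-sequence-only descriptors: AA identity, adjacent neighbors, LGDP.

The adjacent query neighbors (AQN) of residue *i* are the amino-acid
identities at sequence positions *i−1* and *i+1*, read off the FASTA query
itself (so they exist even where homology information does not).  At a chain
terminus the missing neighbor is coded as a distinguished *boundary* level
(its own category under dummy coding); an undefined residue ('X') appearing
as a neighbor is assumed to be alanine for the purposes of neighbor analysis
only.

The Lobanov–Galzitskaya disorder probability (LGDP) is a per-residue
intrinsic-disorder propensity in [0, 1] produced externally (e.g. by
IsUnstruct) and consumed here as a quantitative descriptor.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .io_formats import (
    BOUNDARY,
    UNDEFINED_AA,
    ChainSequence,
    ParseError,
    ResidueRecord,
)
from .homology_descriptors import (
    AlignmentProfile,
    AminoClassScheme,
    DEFAULT_SIX_CLASSES,
    profile_descriptors,
)

logger = logging.getLogger("rsalogit")

__all__ = [
    "ResidueRecord",
    "aqn_neighbors",
    "attach_lgdp",
    "resolve_query_x",
    "build_residue_records",
    "derive_aqn",
]


def aqn_neighbors(seq: ChainSequence, k: int) -> tuple[str, str]:
    """Adjacent query neighbors (previous, next) of 1-based position ``k``.

    Termini yield the boundary marker; an 'X' neighbor is reported as
    alanine.
    """
    if not 1 <= k <= len(seq):
        raise IndexError(
            f"position {k} out of range 1..{len(seq)} for chain "
            f"{seq.chain_id!r}"
        )
    prev = seq.residue(k - 1) if k > 1 else BOUNDARY
    nxt = seq.residue(k + 1) if k < len(seq) else BOUNDARY
    if prev == UNDEFINED_AA:
        prev = "A"
    if nxt == UNDEFINED_AA:
        nxt = "A"
    return prev, nxt


def attach_lgdp(
    records: Sequence[ResidueRecord],
    lgdp_table: Mapping[tuple[str, int], float],
) -> list[ResidueRecord]:
    """Fill ``lgdp`` from a table keyed by (chain_id, position), in place.

    Values outside [0, 1] are errors.  Records without an entry keep a
    missing LGDP and remain usable for models that do not include it; the
    coverage fraction is logged.
    """
    n_filled = 0
    for rec in records:
        key = (rec.chain_id, rec.position)
        if key in lgdp_table:
            value = float(lgdp_table[key])
            if not 0.0 <= value <= 1.0:
                raise ParseError(
                    f"{rec.chain_id}:{rec.position}: LGDP {value} outside "
                    f"[0, 1]"
                )
            rec.lgdp = value
            n_filled += 1
    if records:
        logger.info(
            "LGDP coverage: %d/%d records (%.1f%%)",
            n_filled, len(records), 100.0 * n_filled / len(records),
        )
    return list(records)


def resolve_query_x(records: Sequence[ResidueRecord]) -> list[ResidueRecord]:
    """Drop records whose own residue is undefined ('X'), with a logged count.

    Neighbor positions were already resolved to alanine by
    :func:`aqn_neighbors`; the undefined residue itself cannot be dummy-coded
    and is excluded from fitting and evaluation.
    """
    kept = [r for r in records if r.aa != UNDEFINED_AA]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("dropped %d record(s) with undefined query residue", dropped)
    return kept


def build_residue_records(
    chain: ChainSequence,
    profile: AlignmentProfile | None = None,
    scheme: AminoClassScheme = DEFAULT_SIX_CLASSES,
    min_hits: int = 10,
) -> list[ResidueRecord]:
    """One record per chain position, with AQN and (if available) homology
    descriptors attached.

    Without a profile the chain is non-optimum by definition and homology
    descriptors stay missing.  With a profile, positions where no subject
    residue aligns (``N_k = 0``) also get missing homology descriptors, even
    inside an optimum-homology chain; they are excluded from homology-model
    fitting downstream.
    """
    records: list[ResidueRecord] = []
    if profile is not None:
        if profile.length != len(chain):
            raise ParseError(
                f"chain {chain.chain_id!r}: profile length {profile.length} "
                f"!= sequence length {len(chain)}"
            )
        e20a, e6a, fshpa, fsra, n_k, status = profile_descriptors(
            profile, scheme=scheme, min_hits=min_hits
        )
    for k in range(1, len(chain) + 1):
        prev, nxt = aqn_neighbors(chain, k)
        rec = ResidueRecord(
            chain_id=chain.chain_id,
            position=k,
            aa=chain.residue(k),
            aqn_prev=prev,
            aqn_next=nxt,
        )
        if profile is None:
            rec.n_hits = 0
            rec.homology_status = "non_optimum"
        else:
            rec.n_hits = profile.n_hits
            rec.homology_status = status
            rec.n_aligned = int(n_k[k - 1])
            if n_k[k - 1] >= 1:
                rec.e20 = float(e20a[k - 1])
                rec.e6 = float(e6a[k - 1])
                rec.fshp = float(fshpa[k - 1])
                rec.fsr = float(fsra[k - 1])
        records.append(rec)
    return records


def derive_aqn(records: Sequence[ResidueRecord]) -> list[ResidueRecord]:
    """Fill missing ``aqn_prev``/``aqn_next`` from neighboring records.

    For residue CSVs that carry ``aa`` but not the neighbor columns: the
    neighbor at position k∓1 within the same chain supplies the level, the
    boundary marker is used where no such record exists, and 'X' neighbors
    become alanine.
    """
    by_pos = {(r.chain_id, r.position): r for r in records}

    def neighbor_level(chain_id: str, pos: int) -> str:
        rec = by_pos.get((chain_id, pos))
        if rec is None or rec.aa is None:
            return BOUNDARY
        return "A" if rec.aa == UNDEFINED_AA else rec.aa

    for rec in records:
        if rec.aqn_prev is None:
            rec.aqn_prev = neighbor_level(rec.chain_id, rec.position - 1)
        if rec.aqn_next is None:
            rec.aqn_next = neighbor_level(rec.chain_id, rec.position + 1)
    return list(records)
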