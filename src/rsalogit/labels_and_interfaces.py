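"""Binary burial labels from RSA values, and interfacial-residue flagging.

A residue with relative solvent accessibility below a threshold (20% by
default; 25% is the standard alternative) is *buried* (label 0); at or above
the threshold it is *accessible* (label 1).

For oligomeric chains, accessibility computed on the isolated chain differs
from accessibility computed in the biological-unit complex wherever the
residue touches another chain: burial by a partner can only lower the
complex-context value.  Residues whose single-chain RSA exceeds their
complex-context RSA by more than ``min_delta`` (default 0, i.e. any
measurable increase) are flagged *likely interfacial*.  Gold-standard labels
for oligomer chains use the complex-context value — the biological unit is
the physically relevant state.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .io_formats import (
    COMPLEX,
    SINGLE_CHAIN,
    EvaluationError,
    ResidueRecord,
    RsaTable,
)

logger = logging.getLogger("rsalogit")

DEFAULT_RSA_THRESHOLD = 20.0
ALTERNATIVE_RSA_THRESHOLD = 25.0


def binarize_rsa(rsa: float, threshold: float = DEFAULT_RSA_THRESHOLD) -> int:
    """0 (buried) iff ``rsa < threshold``; 1 (accessible) iff ``rsa >= threshold``."""
    if rsa < 0:
        raise ValueError(f"negative RSA {rsa}")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return 1 if rsa >= threshold else 0


def flag_interfacial(
    single_chain: RsaTable,
    complex_ctx: RsaTable,
    min_delta: float = 0.0,
) -> set[int]:
    """Positions where single-chain RSA exceeds complex-context RSA by more
    than ``min_delta`` percentage points.

    Only positions present in both tables are considered; an empty
    intersection is an error.  A *decrease* on complexation is unphysical
    for a rigid pair but tolerated (simply not flagged).
    """
    common = set(single_chain.values) & set(complex_ctx.values)
    if not common:
        raise EvaluationError(
            f"chains {single_chain.chain_id!r}/{complex_ctx.chain_id!r}: "
            f"no common positions between single-chain and complex RSA"
        )
    return {
        pos for pos in common
        if single_chain.values[pos] - complex_ctx.values[pos] > min_delta
    }


def label_records(
    records: Sequence[ResidueRecord],
    rsa_tables: Mapping[str, Mapping[str, RsaTable]],
    threshold: float = DEFAULT_RSA_THRESHOLD,
    min_delta: float = 0.0,
) -> list[ResidueRecord]:
    """Fill ``rsa``, ``rsa_complex``, ``label`` and ``interfacial`` in place.

    ``rsa_tables`` maps chain_id to a dict with keys ``"single_chain"``
    and/or ``"complex"``.  For oligomer chains with a complex-context table,
    the label uses the complex value and interfacial flags come from the
    single-vs-complex delta; otherwise the single-chain value labels the
    residue.  Records without any RSA entry keep a missing label (excluded
    from evaluation); coverage gaps are logged per chain.
    """
    interfacial_by_chain: dict[str, set[int]] = {}
    for chain_id, tables in rsa_tables.items():
        if SINGLE_CHAIN in tables and COMPLEX in tables:
            interfacial_by_chain[chain_id] = flag_interfacial(
                tables[SINGLE_CHAIN], tables[COMPLEX], min_delta=min_delta
            )

    missing_by_chain: dict[str, int] = {}
    for rec in records:
        tables = rsa_tables.get(rec.chain_id)
        if tables is None:
            missing_by_chain[rec.chain_id] = missing_by_chain.get(rec.chain_id, 0) + 1
            continue
        single = tables.get(SINGLE_CHAIN)
        cplx = tables.get(COMPLEX)
        if single is not None and rec.position in single.values:
            rec.rsa = single.values[rec.position]
        if cplx is not None and rec.position in cplx.values:
            rec.rsa_complex = cplx.values[rec.position]
        label_rsa = None
        if rec.oligomer and rec.rsa_complex is not None:
            label_rsa = rec.rsa_complex
        elif rec.rsa is not None:
            label_rsa = rec.rsa
        elif rec.rsa_complex is not None:
            label_rsa = rec.rsa_complex
        if label_rsa is None:
            missing_by_chain[rec.chain_id] = missing_by_chain.get(rec.chain_id, 0) + 1
            continue
        rec.label = binarize_rsa(label_rsa, threshold)
        flagged = interfacial_by_chain.get(rec.chain_id)
        if flagged is not None:
            rec.interfacial = rec.position in flagged
    for chain_id, count in sorted(missing_by_chain.items()):
        logger.info("chain %s: %d record(s) without RSA — label left missing",
                    chain_id, count)
    return list(records)
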