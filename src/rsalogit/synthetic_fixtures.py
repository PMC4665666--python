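"""Synthetic chains, alignments, RSA tables and disorder propensities with
known ground truth.

The generator emulates the statistical structure of a homology-annotated
X-ray learning set so every pipeline stage is testable without downloads:

* alignment columns are Dirichlet-multinomial — a per-position concentration
  mixes strongly conserved sites (entropy near 0) with variable ones, giving
  a realistic spread of E6/E20 values;
* bit scores spread below and above 40% of the best score so the hit filter
  is exercised; a configurable fraction of chains receives too few homologs
  and lands on the non-optimum branch;
* burial labels are drawn from the logistic model itself at a known true
  coefficient vector (by default the published classic-model coefficients),
  so maximum-likelihood recovery of the truth is the central end-to-end
  check;
* a continuous RSA consistent with each label is sampled uniformly within
  the buried or accessible band, so the linear baseline can be tested
  against the same truth;
* for oligomer chains, a configurable fraction (default one-fifth) of
  residues is interfacial: their single-chain RSA is raised above the
  complex-context value, and (by default) their labels are re-drawn at
  random — decoupled from the descriptors — emulating the degraded
  predictability of interface residues.

A fixed seed fully determines every output, file bytes included.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    COMPLEX,
    GAP,
    SINGLE_CHAIN,
    STANDARD_AA,
    ChainSequence,
    PairwiseHit,
    ResidueRecord,
    RsaTable,
    write_alignment_table,
    write_fasta,
    write_naccess_rsa,
)
from .homology_descriptors import (
    AminoClassScheme,
    DEFAULT_SIX_CLASSES,
    build_profile,
    filter_hits,
)
from .labels_and_interfaces import label_records
from .logit_model import AA_ONE_TO_THREE, PUBLISHED_CLASSIC_COEFFICIENTS
from .sequence_descriptors import build_residue_records, resolve_query_x


def default_true_beta() -> dict[str, float]:
    """Published classic-model coefficients as the generative truth."""
    return {c: v[0] for c, v in PUBLISHED_CLASSIC_COEFFICIENTS.items()}


@dataclass
class FixtureConfig:
    """Everything the generator needs; the seed fully determines the output.

    Defaults emulate the study regime: roughly half the chains oligomeric,
    about one-fifth of oligomer residues interfacial, labels generated from
    the published classic coefficients, a 40%-of-best bit-score filter and a
    ten-hit optimum-homology rule downstream.
    """

    n_chains: int = 30
    chain_length_range: tuple[int, int] = (60, 220)
    mean_hits: float = 24.0
    low_homology_fraction: float = 0.25
    mean_hits_low: float = 5.0
    conserved_fraction: float = 0.5
    alpha_conserved: float = 0.08
    alpha_variable: float = 1.2
    bitscore_best_range: tuple[float, float] = (80.0, 300.0)
    bitscore_rel_range: tuple[float, float] = (0.15, 1.0)
    subject_gap_prob: float = 0.05
    query_gap_prob: float = 0.02
    truncation_prob: float = 0.3
    true_beta: dict[str, float] = field(default_factory=default_true_beta)
    rsa_threshold: float = 20.0
    oligomer_fraction: float = 0.5
    interfacial_fraction: float = 0.2
    interfacial_delta: float = 15.0
    shuffle_interfacial_labels: bool = True
    lgdp_signal: float = 0.6
    lgdp_noise_sd: float = 0.8
    bitscore_fraction: float = 0.4
    min_hits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("low_homology_fraction", "conserved_fraction",
                     "oligomer_fraction", "interfacial_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chain_length_range"] = list(self.chain_length_range)
        d["bitscore_best_range"] = list(self.bitscore_best_range)
        d["bitscore_rel_range"] = list(self.bitscore_rel_range)
        return d


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_from_columns(cum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a cumulative-probability matrix."""
    u = rng.random(cum.shape[0])
    return (u[:, None] > cum).sum(axis=1).clip(0, 19)


def simulate_alignment(
    config: FixtureConfig,
    rng,
    chain_id: str = "syn000a",
    low_homology: bool = False,
) -> tuple[ChainSequence, list[PairwiseHit]]:
    """One query chain plus its (unfiltered) homolog hits.

    Each position gets a Dirichlet column composition; the query and every
    subject letter are drawn from it, so conservation couples the query to
    its family.  Bit scores are the best score times a relative factor
    spanning the 40% cut.  Subject gaps, query-gap (insertion) columns and
    truncated coverage are sprinkled in at low rates to exercise the profile
    builder.
    """
    rng = _rng(rng)
    lo, hi = config.chain_length_range
    length = int(rng.integers(lo, hi + 1))
    conserved = rng.random(length) < config.conserved_fraction
    alphas = np.where(conserved, config.alpha_conserved, config.alpha_variable)
    comps = np.stack([rng.dirichlet(np.full(20, a)) for a in alphas])
    cum = comps.cumsum(axis=1)
    query_idx = _draw_from_columns(cum, rng)
    chain = ChainSequence(
        chain_id=chain_id,
        sequence="".join(STANDARD_AA[i] for i in query_idx),
    )

    mean = config.mean_hits_low if low_homology else config.mean_hits
    n_hits = int(rng.poisson(mean))
    best = float(rng.uniform(*config.bitscore_best_range))
    hits: list[PairwiseHit] = []
    for h in range(n_hits):
        rel = 1.0 if h == 0 else float(rng.uniform(*config.bitscore_rel_range))
        score = round(best * rel, 1)
        start, end = 1, length
        if length > 20 and rng.random() < config.truncation_prob:
            start = int(rng.integers(1, length // 5 + 1))
            end = int(rng.integers(length - length // 5, length + 1))
        span = end - start + 1
        sub_idx = _draw_from_columns(cum[start - 1:end], rng)
        sub_gap = rng.random(span) < config.subject_gap_prob
        insertion = rng.random(span) < config.query_gap_prob
        ins_letters = rng.integers(0, 20, size=span)
        qseq: list[str] = []
        sseq: list[str] = []
        for j in range(span):
            qseq.append(chain.sequence[start - 1 + j])
            sseq.append(GAP if sub_gap[j] else STANDARD_AA[sub_idx[j]])
            if insertion[j]:
                qseq.append(GAP)
                sseq.append(STANDARD_AA[ins_letters[j]])
        hits.append(
            PairwiseHit(
                query_id=chain_id,
                subject_id=f"{chain_id}_h{h:03d}",
                bit_score=score,
                query_start=start,
                aligned_query="".join(qseq),
                aligned_subject="".join(sseq),
            )
        )
    return chain, hits


def linear_predictor(rec: ResidueRecord, true_beta: dict[str, float]) -> float:
    """Evaluate the generative linear predictor for one record.

    Descriptors missing from the record (e.g. homology descriptors on
    uncovered positions) contribute zero, so every record — including
    non-optimum-homology ones — receives a label from the same mechanism.
    """
    eta = true_beta.get("Intercept", 0.0)
    for key, fieldname in (("E20", "e20"), ("E6", "e6"), ("FSHP", "fshp"),
                           ("FSR", "fsr"), ("LGDP", "lgdp")):
        coef = true_beta.get(key)
        if coef is None:
            continue
        value = getattr(rec, fieldname)
        if value is not None and not (isinstance(value, float) and np.isnan(value)):
            eta += coef * value
    if rec.aa is not None and rec.aa in AA_ONE_TO_THREE:
        eta += true_beta.get(f"AA:{AA_ONE_TO_THREE[rec.aa]}", 0.0)
    return eta


def simulate_labels(
    records: list[ResidueRecord],
    true_beta: dict[str, float],
    rng,
    rsa_threshold: float = 20.0,
    lgdp_signal: float = 0.6,
    lgdp_noise_sd: float = 0.8,
) -> list[ResidueRecord]:
    """Draw Y ~ Bernoulli(p) with p = logistic(eta) at the true coefficients,
    and a continuous RSA consistent with the label.

    Accessible residues get RSA uniform on [threshold, 100], buried ones
    uniform on [0, threshold), so thresholding the RSA reproduces the label
    exactly and the linear baseline sees the same truth.  A stub LGDP —
    standing in for an external disorder predictor — is filled as a noisy
    logistic transform of eta, correlated with accessibility.
    """
    rng = _rng(rng)
    from scipy.special import expit

    for rec in records:
        eta = linear_predictor(rec, true_beta)
        rec.lgdp = float(
            expit(lgdp_signal * eta + lgdp_noise_sd * rng.standard_normal())
        )
        p = float(expit(eta))
        label = int(rng.random() < p)
        rec.label = label
        if label:
            rec.rsa = float(rng.uniform(rsa_threshold, 100.0))
        else:
            rec.rsa = float(rng.uniform(0.0, rsa_threshold))
    return records


def simulate_oligomer_context(
    records: list[ResidueRecord],
    config: FixtureConfig,
    rng,
    oligomer_chains: set[str] | None = None,
) -> dict[str, dict[str, RsaTable]]:
    """Designate interfacial residues and build paired RSA tables.

    For every oligomer chain, each residue is interfacial with probability
    ``interfacial_fraction``; interfacial residues get their single-chain
    RSA raised ``interfacial_delta`` percentage points above the complex
    value.  With ``shuffle_interfacial_labels`` (the default), interfacial
    labels are re-drawn fair-coin — decoupling them from the descriptors, as
    real interface burial is invisible to single-chain descriptors — and the
    complex RSA is re-sampled consistently.  Labels always follow the
    complex-context RSA.
    """
    rng = _rng(rng)
    by_chain: dict[str, list[ResidueRecord]] = {}
    for rec in records:
        by_chain.setdefault(rec.chain_id, []).append(rec)
    if oligomer_chains is None:
        oligomer_chains = {c for c in by_chain
                           if rng.random() < config.oligomer_fraction}

    tables: dict[str, dict[str, RsaTable]] = {}
    thr = config.rsa_threshold
    for chain_id, chain_records in by_chain.items():
        is_oligo = chain_id in oligomer_chains
        single: dict[int, float] = {}
        cplx: dict[int, float] = {}
        for rec in chain_records:
            rec.oligomer = is_oligo
            if rec.rsa is None:
                continue
            if not is_oligo:
                single[rec.position] = round(rec.rsa, 1)
                continue
            interfacial = bool(rng.random() < config.interfacial_fraction)
            if interfacial and config.shuffle_interfacial_labels:
                new_label = int(rng.random() < 0.5)
                rec.label = new_label
                rec.rsa = (
                    float(rng.uniform(thr, 100.0)) if new_label
                    else float(rng.uniform(0.0, thr))
                )
            complex_rsa = round(rec.rsa, 1)
            cplx[rec.position] = complex_rsa
            single[rec.position] = round(
                complex_rsa + (config.interfacial_delta if interfacial else 0.0),
                1,
            )
        tables[chain_id] = {
            SINGLE_CHAIN: RsaTable(chain_id=chain_id, values=single,
                                   context=SINGLE_CHAIN),
        }
        if is_oligo:
            tables[chain_id][COMPLEX] = RsaTable(
                chain_id=chain_id, values=cplx, context=COMPLEX
            )
    return tables


@dataclass
class SimulatedData:
    """A complete synthetic study: inputs, intermediates and ground truth."""

    config: FixtureConfig
    chains: list[ChainSequence]
    hits_by_chain: dict[str, list[PairwiseHit]]
    records: list[ResidueRecord]
    rsa_tables: dict[str, dict[str, RsaTable]]
    oligomer_chains: set[str]


def simulate_dataset(
    config: FixtureConfig | None = None,
    scheme: AminoClassScheme = DEFAULT_SIX_CLASSES,
) -> SimulatedData:
    """Run the full generative pipeline at ``config.seed``.

    Chains and alignments are simulated, descriptors computed through the
    same code paths the real pipeline uses (hit filter, profile, entropies,
    neighbors), labels drawn from the true coefficients, oligomer/interface
    structure added, and finally RSA tables are re-applied through the
    labelling stage so every field is pipeline-consistent.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    chains: list[ChainSequence] = []
    hits_by_chain: dict[str, list[PairwiseHit]] = {}
    records: list[ResidueRecord] = []
    for i in range(config.n_chains):
        chain_id = f"syn{i:03d}a"
        low = rng.random() < config.low_homology_fraction
        chain, hits = simulate_alignment(config, rng, chain_id, low_homology=low)
        chains.append(chain)
        hits_by_chain[chain_id] = hits
        kept = filter_hits(hits, config.bitscore_fraction)
        profile = build_profile(chain, kept)
        records.extend(
            build_residue_records(chain, profile, scheme=scheme,
                                  min_hits=config.min_hits)
        )
    records = resolve_query_x(records)
    simulate_labels(
        records, config.true_beta, rng,
        rsa_threshold=config.rsa_threshold,
        lgdp_signal=config.lgdp_signal,
        lgdp_noise_sd=config.lgdp_noise_sd,
    )
    rsa_tables = simulate_oligomer_context(records, config, rng)
    oligomer_chains = {c for c, t in rsa_tables.items() if COMPLEX in t}
    # Re-derive rsa/label/interfacial through the labelling stage so the
    # in-memory records match what a run over the written files produces.
    label_records(records, rsa_tables, threshold=config.rsa_threshold)
    return SimulatedData(
        config=config,
        chains=chains,
        hits_by_chain=hits_by_chain,
        records=records,
        rsa_tables=rsa_tables,
        oligomer_chains=oligomer_chains,
    )


def write_fixture(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture directory.

    FASTA, alignment TSV (unfiltered hits — the pipeline applies the
    bit-score filter), per-chain ``.rsa`` files (plus ``.complex.rsa`` for
    oligomers), an LGDP CSV, and a manifest JSON carrying the config, the
    oligomer flags and the true coefficients.  Bytes are reproducible at a
    fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rsa_dir = outdir / "rsa"
    rsa_dir.mkdir(exist_ok=True)

    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "chains.fasta"
    write_fasta(data.chains, paths["fasta"])

    paths["alignments"] = outdir / "alignments.tsv"
    all_hits = [h for c in data.chains for h in data.hits_by_chain[c.chain_id]]
    write_alignment_table(all_hits, paths["alignments"])

    seq_by_chain = {c.chain_id: c.sequence for c in data.chains}
    for chain_id, tables in sorted(data.rsa_tables.items()):
        single_path = rsa_dir / f"{chain_id}.rsa"
        write_naccess_rsa(tables[SINGLE_CHAIN], seq_by_chain[chain_id],
                          single_path)
        if COMPLEX in tables:
            write_naccess_rsa(tables[COMPLEX], seq_by_chain[chain_id],
                              rsa_dir / f"{chain_id}.complex.rsa")
    paths["rsa_dir"] = rsa_dir

    paths["lgdp"] = outdir / "lgdp.csv"
    with open(paths["lgdp"], "w") as fh:
        fh.write("chain_id,position,lgdp\n")
        for rec in data.records:
            if rec.lgdp is not None:
                fh.write(f"{rec.chain_id},{rec.position},{rec.lgdp:.6f}\n")

    paths["manifest"] = outdir / "manifest.json"
    manifest = {
        "config": data.config.to_dict(),
        "oligomer": {c.chain_id: (c.chain_id in data.oligomer_chains)
                     for c in data.chains},
        "true_beta": dict(data.config.true_beta),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
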