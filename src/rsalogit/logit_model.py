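"""Design-matrix assembly, logistic maximum likelihood, Wald inference,
prediction, and the linear least-squares baseline.

The response is burial status: Y = 0 for buried residues, Y = 1 for
accessible residues.  The linear predictor combines quantitative descriptors
(entropies, aligned-residue fractions, disorder propensity) with
dummy-coded qualitative descriptors — the query amino-acid type AA (19
indicator variables, treatment coding with Val as the baseline) and
optionally the two adjacent-neighbor factors.  The odds of accessibility are
the exponentiated linear predictor,

    p / (1 - p) = exp(b0 + sum_q b_q X_q + sum_j b_j X_j),

so exp(b) is the multiplicative change in accessibility odds per unit
increase of a descriptor (or relative to the baseline level, for an
indicator).  Coefficients are estimated by maximum likelihood via
iteratively reweighted least squares (Newton-Raphson on the Bernoulli
log-likelihood); standard errors come from the inverse observed information
at the optimum, and Wald z = b/SE is referred to the standard normal for
two-sided p-values.  No regularization is applied anywhere: separation and
rank deficiency are flagged, never silently penalized.

Entropies enter in nats; coefficient magnitudes (not accuracies) depend on
that choice, so the logarithm base is recorded in the model JSON.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla
from scipy.special import expit
from scipy.stats import norm

from .io_formats import (
    AA_ONE_TO_THREE,
    AA_THREE_TO_ONE,
    ModelError,
    ResidueRecord,
)

logger = logging.getLogger("rsalogit")

QUANTITATIVE_DESCRIPTORS = ("E20", "E6", "FSHP", "FSR", "LGDP")
CATEGORICAL_DESCRIPTORS = ("AA", "AQN_prev", "AQN_next")
ALL_DESCRIPTORS = QUANTITATIVE_DESCRIPTORS + CATEGORICAL_DESCRIPTORS

#: Record attribute backing each descriptor.
_DESCRIPTOR_FIELD = {
    "E20": "e20", "E6": "e6", "FSHP": "fshp", "FSR": "fsr", "LGDP": "lgdp",
    "AA": "aa", "AQN_prev": "aqn_prev", "AQN_next": "aqn_next",
}

NAMED_MODELS = {
    "classic": ("E20", "E6", "FSR", "FSHP", "AA"),
    "comprehensive": ("E6", "FSR", "FSHP", "AA", "LGDP", "AQN_prev", "AQN_next"),
    "non_homology": ("LGDP", "AA", "AQN_prev", "AQN_next"),
}

INTERCEPT = "Intercept"


# --------------------------------------------------------------------------
# Model specification and design matrix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which descriptors enter the model, and coding/threshold conventions."""

    descriptors: tuple[str, ...]
    baseline: Mapping[str, str] = field(
        default_factory=lambda: {"AA": "V", "AQN_prev": "V", "AQN_next": "V"}
    )
    rsa_threshold: float = 20.0
    classification_cutoff: float = 0.5
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.descriptors:
            raise ModelError("a model needs at least one descriptor")
        unknown = set(self.descriptors) - set(ALL_DESCRIPTORS)
        if unknown:
            raise ModelError(f"unknown descriptor(s) {sorted(unknown)}")
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        object.__setattr__(self, "baseline", dict(self.baseline))

    @classmethod
    def named(cls, name: str, **overrides) -> "ModelSpec":
        """One of the supported named models: classic, comprehensive,
        non_homology."""
        if name not in NAMED_MODELS:
            raise ModelError(
                f"unknown model name {name!r}; supported: "
                f"{sorted(NAMED_MODELS)}"
            )
        return cls(descriptors=NAMED_MODELS[name], name=name, **overrides)

    @property
    def quantitative(self) -> tuple[str, ...]:
        return tuple(d for d in self.descriptors if d in QUANTITATIVE_DESCRIPTORS)

    @property
    def categorical(self) -> tuple[str, ...]:
        return tuple(d for d in self.descriptors if d in CATEGORICAL_DESCRIPTORS)


def _column_label(factor: str, level: str) -> str:
    if factor == "AA":
        return f"AA:{AA_ONE_TO_THREE[level]}"
    return f"{factor}:{level}"


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def complete_records(
    records: Sequence[ResidueRecord],
    spec: ModelSpec,
    require_label: bool = True,
) -> list[ResidueRecord]:
    """Records complete for every descriptor of ``spec`` (and the label).

    Records missing a required field are excluded from this model only; the
    count is logged.
    """
    needed = [_DESCRIPTOR_FIELD[d] for d in spec.descriptors]
    kept = []
    for rec in records:
        if require_label and _is_missing(rec.label):
            continue
        if any(_is_missing(getattr(rec, f)) for f in needed):
            continue
        kept.append(rec)
    dropped = len(records) - len(kept)
    if dropped:
        logger.info(
            "model %s: %d/%d record(s) incomplete and excluded",
            spec.name or "+".join(spec.descriptors), dropped, len(records),
        )
    return kept


@dataclass
class DesignMatrix:
    """Numeric encoding of residue records aligned to the response vector.

    Quantitative descriptors enter as-is; each categorical factor expands to
    0/1 indicators for every non-baseline level (treatment coding), ordered
    alphabetically within the factor.  Row provenance maps back to
    (chain_id, position).
    """

    X: np.ndarray
    y: np.ndarray | None
    columns: list[str]
    levels: dict[str, list[str]]
    provenance: list[tuple[str, int]]
    spec: ModelSpec


def _encode(
    records: Sequence[ResidueRecord],
    spec: ModelSpec,
    levels: Mapping[str, Sequence[str]] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Shared encoder for fitting (levels learned) and prediction (levels
    fixed by the fit)."""
    fixed = levels is not None
    learned: dict[str, list[str]] = {}
    for factor in spec.categorical:
        base = spec.baseline.get(factor)
        if base is None:
            raise ModelError(f"no baseline level declared for factor {factor}")
        if fixed:
            learned[factor] = list(levels[factor])
        else:
            observed = {
                getattr(r, _DESCRIPTOR_FIELD[factor]) for r in records
            }
            learned[factor] = sorted(
                (lvl for lvl in observed if lvl != base),
                key=lambda lvl: _column_label(factor, lvl),
            )
    columns = [INTERCEPT]
    columns.extend(spec.quantitative)
    for factor in spec.categorical:
        columns.extend(_column_label(factor, lvl) for lvl in learned[factor])

    n, p = len(records), len(columns)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    col_of = {c: j for j, c in enumerate(columns)}
    for i, rec in enumerate(records):
        for q in spec.quantitative:
            value = getattr(rec, _DESCRIPTOR_FIELD[q])
            if _is_missing(value):
                raise ModelError(
                    f"{rec.chain_id}:{rec.position}: missing descriptor {q}"
                )
            X[i, col_of[q]] = value
        for factor in spec.categorical:
            level = getattr(rec, _DESCRIPTOR_FIELD[factor])
            if _is_missing(level):
                raise ModelError(
                    f"{rec.chain_id}:{rec.position}: missing descriptor "
                    f"{factor}"
                )
            if level == spec.baseline[factor]:
                continue
            label = _column_label(factor, level)
            if label not in col_of:
                raise ModelError(
                    f"{rec.chain_id}:{rec.position}: level {level!r} of "
                    f"factor {factor} absent from the learning set"
                )
            X[i, col_of[label]] = 1.0
    return X, columns, learned


def build_design(records: Sequence[ResidueRecord], spec: ModelSpec) -> DesignMatrix:
    """Assemble the design matrix and response for fitting.

    Every record must be complete for the spec's descriptors and carry a
    label (filter with :func:`complete_records` first if needed).
    """
    if not records:
        raise ModelError("no records to encode")
    for rec in records:
        if _is_missing(rec.label):
            raise ModelError(
                f"{rec.chain_id}:{rec.position}: record has no label"
            )
    X, columns, levels = _encode(records, spec)
    y = np.array([rec.label for rec in records], dtype=float)
    return DesignMatrix(
        X=X,
        y=y,
        columns=columns,
        levels=levels,
        provenance=[(r.chain_id, r.position) for r in records],
        spec=spec,
    )


# --------------------------------------------------------------------------
# Logistic maximum likelihood (IRLS)
# --------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood coefficients with Wald inference.

    ``beta`` is on the log-odds scale; ``exp(beta)`` is the odds ratio per
    unit increase (or versus the baseline level).  ``converged`` reflects the
    optimizer status — separation and rank deficiency leave it False with a
    diagnostic naming the offending columns.
    """

    spec: ModelSpec
    columns: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_records: int
    converged: bool
    n_iter: int
    levels: dict[str, list[str]]
    diagnostic: str | None = None

    @property
    def z(self) -> dict[str, float]:
        return {c: self.beta[c] / self.se[c] for c in self.columns}

    @property
    def p_values(self) -> dict[str, float]:
        return {c: 2.0 * norm.sf(abs(z)) for c, z in self.z.items()}

    @property
    def exp_beta(self) -> dict[str, float]:
        return {c: math.exp(self.beta[c]) for c in self.columns}

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "descriptors": list(self.spec.descriptors),
            "baseline": dict(self.spec.baseline),
            "rsa_threshold": self.spec.rsa_threshold,
            "classification_cutoff": self.spec.classification_cutoff,
            "entropy_log_base": "e",
            "columns": list(self.columns),
            "beta": dict(self.beta),
            "se": dict(self.se),
            "levels": {k: list(v) for k, v in self.levels.items()},
            "loglik": self.loglik,
            "n_records": self.n_records,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticFit":
        for key in ("descriptors", "baseline", "columns", "beta", "se", "levels"):
            if key not in d:
                raise KeyError(f"missing {key!r} key")
        spec = ModelSpec(
            descriptors=tuple(d["descriptors"]),
            baseline=dict(d["baseline"]),
            rsa_threshold=float(d.get("rsa_threshold", 20.0)),
            classification_cutoff=float(d.get("classification_cutoff", 0.5)),
            name=d.get("name"),
        )
        columns = list(d["columns"])
        beta = {k: float(v) for k, v in d["beta"].items()}
        se = {k: float(v) for k, v in d["se"].items()}
        missing = [c for c in columns if c not in beta]
        if missing:
            raise KeyError(f"missing coefficient(s) for column(s) {missing}")
        return cls(
            spec=spec,
            columns=columns,
            beta=beta,
            se=se,
            loglik=float(d.get("loglik", float("nan"))),
            n_records=int(d.get("n_records", 0)),
            converged=bool(d.get("converged", True)),
            n_iter=int(d.get("n_iter", 0)),
            levels={k: list(v) for k, v in d["levels"].items()},
        )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _rank_deficient_columns(X: np.ndarray, columns: list[str]) -> list[str]:
    """Names of columns made redundant by the others (QR with pivoting)."""
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [columns[j] for j in sorted(piv[rank:])]


def fit_logistic(
    design: DesignMatrix,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit by IRLS (Newton-Raphson), converging on relative log-likelihood
    change below ``tol``.

    Requires at least one record of each class and no constant-zero column.
    Perfect separation and rank deficiency yield a non-converged fit whose
    ``diagnostic`` names the offending columns.
    """
    X, y = design.X, design.y
    if y is None:
        raise ModelError("design has no response vector")
    n, p = X.shape
    if n == 0:
        raise ModelError("empty design matrix")
    if y.min() == y.max():
        raise ModelError(
            f"all {n} records are of class {int(y[0])}; both classes are "
            f"required to fit"
        )
    zero_cols = [design.columns[j] for j in range(p)
                 if not np.any(X[:, j])]
    if zero_cols:
        raise ModelError(f"constant-zero column(s) {zero_cols}")

    beta = np.zeros(p)
    ll_old = -np.inf
    ll = _bernoulli_loglik(y, X @ beta)
    converged = False
    diagnostic = None
    hessian = None
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        hessian = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = sla.solve(hessian, score, assume_a="pos")
        except (sla.LinAlgError, ValueError):
            if np.abs(beta).max() > 10:
                order = np.argsort(-np.abs(beta))
                diagnostic = (
                    "perfect or quasi-perfect separation; runaway "
                    f"column(s): {[design.columns[j] for j in order[:3]]}"
                )
            else:
                diagnostic = (
                    "singular information matrix; redundant column(s): "
                    f"{_rank_deficient_columns(X, design.columns)}"
                )
            break
        beta = beta + step
        ll = _bernoulli_loglik(y, X @ beta)
        if abs(ll - ll_old) <= tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll

    if diagnostic is None and (not converged or ll > -1e-8 * n):
        # A log-likelihood at (numerically) zero means every record is
        # classified perfectly: separation, coefficients diverging.
        order = np.argsort(-np.abs(beta))
        worst = [design.columns[j] for j in order[:3] if abs(beta[j]) > 10]
        if ll > -1e-8 * n or worst:
            converged = False
            diagnostic = (
                "perfect or quasi-perfect separation; runaway column(s): "
                f"{worst or [design.columns[j] for j in order[:3]]}"
            )

    # Wald standard errors from the inverse observed information.
    se = np.full(p, np.nan)
    if hessian is not None:
        try:
            cov = sla.inv(hessian)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = np.sqrt(diag)
            elif converged:
                converged = False
                diagnostic = "non-positive variance estimate at the optimum"
        except sla.LinAlgError:
            if converged:
                converged = False
                diagnostic = "information matrix not invertible at the optimum"

    fit = LogisticFit(
        spec=design.spec,
        columns=list(design.columns),
        beta={c: float(b) for c, b in zip(design.columns, beta)},
        se={c: float(s) for c, s in zip(design.columns, se)},
        loglik=ll,
        n_records=n,
        converged=converged,
        n_iter=it,
        levels={k: list(v) for k, v in design.levels.items()},
        diagnostic=diagnostic,
    )
    if not converged:
        logger.warning("logistic fit did not converge: %s", diagnostic)
    return fit


def odds_ratio(fit: LogisticFit, column: str, delta: float = 1.0) -> float:
    """exp(delta * beta_column): the change in accessibility odds for a
    ``delta``-unit increase of the descriptor."""
    if column not in fit.beta:
        raise ModelError(
            f"unknown column {column!r}; available: {fit.columns}"
        )
    return math.exp(delta * fit.beta[column])


# --------------------------------------------------------------------------
# Prediction and classification
# --------------------------------------------------------------------------

def predict_eta(fit: LogisticFit, records: Sequence[ResidueRecord]) -> np.ndarray:
    """Linear predictor per record (NaN where a descriptor is missing)."""
    out = np.full(len(records), np.nan)
    usable_idx = []
    usable = []
    for i, rec in enumerate(records):
        if any(
            _is_missing(getattr(rec, _DESCRIPTOR_FIELD[d]))
            for d in fit.spec.descriptors
        ):
            continue
        usable_idx.append(i)
        usable.append(rec)
    skipped = len(records) - len(usable)
    if skipped:
        logger.info("prediction: %d record(s) skipped (missing descriptors)",
                    skipped)
    if not usable:
        return out
    X, columns, _ = _encode(usable, fit.spec, levels=fit.levels)
    b = np.array([fit.beta[c] for c in columns])
    out[usable_idx] = X @ b
    return out


def predict_proba(fit: LogisticFit, records: Sequence[ResidueRecord]) -> np.ndarray:
    """Accessibility probability p = exp(eta)/(1+exp(eta)) per record.

    Numerically stable for large |eta|; NaN where a required descriptor is
    missing (skipped records are reported via the log).
    """
    return expit(predict_eta(fit, records))


def classify(probabilities: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """1 (accessible) iff p >= cutoff; the boundary is inclusive."""
    p = np.asarray(probabilities, dtype=float)
    if np.isnan(p).any():
        raise ModelError("cannot classify missing probabilities")
    if ((p < 0) | (p > 1)).any():
        raise ModelError("probabilities outside [0, 1]")
    return (p >= cutoff).astype(int)


# --------------------------------------------------------------------------
# Linear least-squares baseline (continuous RSA regressed on one
# quantitative descriptor + AA)
# --------------------------------------------------------------------------

@dataclass
class LinearBaselineFit:
    """OLS of continuous RSA on one quantitative descriptor plus amino-acid
    type: a single common slope with per-AA intercepts."""

    quantitative: str
    slope: float
    intercepts: dict[str, float]
    rsa_threshold: float
    n_records: int

    def predict_rsa(self, records: Sequence[ResidueRecord]) -> np.ndarray:
        qfield = _DESCRIPTOR_FIELD[self.quantitative]
        out = np.full(len(records), np.nan)
        for i, rec in enumerate(records):
            value = getattr(rec, qfield)
            if _is_missing(value) or rec.aa not in self.intercepts:
                continue
            out[i] = self.intercepts[rec.aa] + self.slope * value
        return out

    def classify(self, records: Sequence[ResidueRecord]) -> np.ndarray:
        """Accessible iff predicted RSA >= threshold (same boundary
        convention as label binarization)."""
        pred = self.predict_rsa(records)
        if np.isnan(pred).any():
            raise ModelError("cannot classify records with missing descriptors")
        return (pred >= self.rsa_threshold).astype(int)


def fit_linear_baseline(
    records: Sequence[ResidueRecord],
    quantitative: str = "E6",
    rsa_threshold: float = 20.0,
) -> LinearBaselineFit:
    """Ordinary least squares of continuous RSA (percent) on one
    quantitative descriptor with amino-acid-specific intercepts.

    The design has one indicator per observed amino acid (no global
    intercept) plus the descriptor column, so the fit has a common slope and
    a varying intercept per residue type.
    """
    if quantitative not in QUANTITATIVE_DESCRIPTORS:
        raise ModelError(f"unknown quantitative descriptor {quantitative!r}")
    qfield = _DESCRIPTOR_FIELD[quantitative]
    usable = [
        r for r in records
        if not _is_missing(getattr(r, qfield))
        and not _is_missing(r.rsa) and not _is_missing(r.aa)
    ]
    if not usable:
        raise ModelError("no records with RSA and the requested descriptor")
    aa_levels = sorted({r.aa for r in usable})
    n, p = len(usable), len(aa_levels) + 1
    X = np.zeros((n, p))
    y = np.empty(n)
    aa_col = {aa: j for j, aa in enumerate(aa_levels)}
    for i, rec in enumerate(usable):
        X[i, aa_col[rec.aa]] = 1.0
        X[i, -1] = getattr(rec, qfield)
        y[i] = rec.rsa
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ModelError(
            "degenerate baseline design (descriptor constant within every "
            "amino-acid type?)"
        )
    return LinearBaselineFit(
        quantitative=quantitative,
        slope=float(coef[-1]),
        intercepts={aa: float(coef[aa_col[aa]]) for aa in aa_levels},
        rsa_threshold=rsa_threshold,
        n_records=n,
    )


# --------------------------------------------------------------------------
# Published reference coefficients
# --------------------------------------------------------------------------

#: Reference fit of the classic model (E20+E6+FSR+FSHP+AA, 20% RSA
#: threshold, natural-log entropies) on the 1363-chain nonredundant X-ray
#: learning set, as published: (beta, SE, exp(beta), Wald z) per design
#: column.  Useful for prediction without refitting and as an arithmetic
#: consistency check on the odds-ratio machinery.
PUBLISHED_CLASSIC_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "Intercept": (-0.528, 0.031, 0.590, -17.247),
    "E20":       (0.342, 0.012, 1.407, 29.162),
    "E6":        (0.862, 0.017, 2.369, 51.156),
    "FSR":       (-0.922, 0.031, 0.398, -29.690),
    "FSHP":      (-1.646, 0.030, 0.193, -54.898),
    "AA:ALA":    (-0.267, 0.034, 0.766, -7.861),
    "AA:ARG":    (0.765, 0.034, 2.149, 22.363),
    "AA:ASN":    (0.358, 0.035, 1.430, 10.236),
    "AA:ASP":    (0.774, 0.034, 2.168, 22.670),
    "AA:CYS":    (-1.543, 0.052, 0.214, -29.405),
    "AA:GLN":    (0.366, 0.036, 1.442, 10.234),
    "AA:GLU":    (0.985, 0.034, 2.677, 29.047),
    "AA:GLY":    (0.829, 0.038, 2.292, 21.588),
    "AA:HIS":    (-0.114, 0.038, 0.893, -3.003),
    "AA:ILE":    (-0.036, 0.027, 0.965, -1.353),
    "AA:LEU":    (0.202, 0.023, 1.224, 8.767),
    "AA:LYS":    (1.509, 0.036, 4.522, 41.384),
    "AA:MET":    (0.269, 0.036, 1.308, 7.424),
    "AA:PHE":    (0.040, 0.030, 1.041, 1.359),
    "AA:PRO":    (0.449, 0.034, 1.567, 13.072),
    "AA:SER":    (-0.166, 0.032, 0.847, -5.113),
    "AA:THR":    (-0.168, 0.032, 0.845, -5.291),
    "AA:TRP":    (0.567, 0.041, 1.763, 13.784),
    "AA:TYR":    (0.690, 0.029, 1.995, 24.195),
}


def published_classic_fit(rsa_threshold: float = 20.0) -> LogisticFit:
    """The published classic-model coefficients wrapped as a
    :class:`LogisticFit`, ready for prediction."""
    spec = ModelSpec.named("classic", rsa_threshold=rsa_threshold)
    columns = list(PUBLISHED_CLASSIC_COEFFICIENTS)
    aa_levels = sorted(
        (AA_THREE_TO_ONE[c.split(":")[1]] for c in columns if c.startswith("AA:")),
        key=lambda lvl: _column_label("AA", lvl),
    )
    return LogisticFit(
        spec=spec,
        columns=columns,
        beta={c: v[0] for c, v in PUBLISHED_CLASSIC_COEFFICIENTS.items()},
        se={c: v[1] for c, v in PUBLISHED_CLASSIC_COEFFICIENTS.items()},
        loglik=float("nan"),
        n_records=0,
        converged=True,
        n_iter=0,
        levels={"AA": aa_levels},
    )


# --------------------------------------------------------------------------
# Fit report (variable / beta / SE / exp(beta) / z / p)
# --------------------------------------------------------------------------

def write_fit_report(fit: LogisticFit, path, metadata: Mapping | None = None) -> None:
    """Write a coefficient table as TSV: variable, beta, SE, exp(beta), z, p."""
    import json as _json

    z = fit.z
    pvals = fit.p_values
    eb = fit.exp_beta
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + _json.dumps(dict(metadata), sort_keys=True) + "\n")
        fh.write("variable\tbeta\tse\texp_beta\tz\tp\n")
        for c in fit.columns:
            fh.write(
                f"{c}\t{fit.beta[c]:.6g}\t{fit.se[c]:.6g}\t{eb[c]:.6g}\t"
                f"{z[c]:.6g}\t{pvals[c]:.3g}\n"
            )
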