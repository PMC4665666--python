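"""Two-state accuracy and the stratified, two-branch evaluation strategy.

Accuracy is the standard two-state fraction correct over both classes,
100 x (TP + TN) / (P + N).

Homology descriptors are unreliable for chains with fewer than ten filtered
homologs, so evaluation branches: optimum-homology records are scored with a
model that may include homology descriptors, non-optimum records with a
model built exclusively from non-homology descriptors.  The headline
*all-proteins* number is the residue-count-weighted mean of the two branch
accuracies (identically the pooled accuracy).

Reports also stratify by oligomer status and by interfacial flagging, and
carry the M/O/P delta coding for accuracy differences: M if the difference
is below -0.5 percentage points, P if above +0.5, otherwise O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import NON_OPTIMUM, OPTIMUM, EvaluationError, ResidueRecord
from .logit_model import LogisticFit, classify, complete_records, predict_proba

logger = logging.getLogger("rsalogit")

STRATA = (
    "all", "optimum", "non_optimum", "oligomer", "non_oligomer",
    "oligomer_without_interface", "interfacial_only",
)


def accuracy(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Percent of residues correctly classified, counting both classes."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise EvaluationError(
            f"length mismatch: {pred.shape} predictions vs {lab.shape} labels"
        )
    if pred.size == 0:
        raise EvaluationError("cannot compute accuracy of an empty set")
    if not np.isin(lab, (0, 1)).all():
        raise EvaluationError("labels must be 0/1")
    return float(100.0 * (pred == lab).mean())


def weighted_accuracy(strata: Sequence[tuple[int, float]]) -> float:
    """Residue-count-weighted mean accuracy over strata of (n, accuracy)."""
    if not strata:
        raise EvaluationError("no strata to weight")
    total = 0
    weighted = 0.0
    for n, acc in strata:
        if n <= 0:
            raise EvaluationError(f"stratum with non-positive count {n}")
        total += n
        weighted += n * acc
    return weighted / total


def delta_code(difference: float, band: float = 0.5) -> str:
    """M if the accuracy difference < -band, P if > +band, otherwise O."""
    if difference < -band:
        return "M"
    if difference > band:
        return "P"
    return "O"


@dataclass
class StratumResult:
    n_residues: int
    accuracy: float


@dataclass
class EvaluationReport:
    """Stratified accuracies with the weighted all-proteins number.

    ``strata`` holds only non-empty strata.  ``delta_codes`` carries the
    M/O/P coding for oligomer-minus-non-oligomer and for the change when
    likely interfacial residues are removed from the oligomer set.
    """

    strata: dict[str, StratumResult]
    weighted_all_proteins: float
    delta_codes: dict[str, str]
    models: dict[str, str]
    rsa_threshold: float
    classification_cutoff: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "strata": {
                name: {"n_residues": s.n_residues, "accuracy": s.accuracy}
                for name, s in self.strata.items()
            },
            "weighted_all_proteins": self.weighted_all_proteins,
            "delta_codes": dict(self.delta_codes),
            "models": dict(self.models),
            "rsa_threshold": self.rsa_threshold,
            "classification_cutoff": self.classification_cutoff,
            "n_excluded": self.n_excluded,
        }


def evaluate(
    records: Sequence[ResidueRecord],
    fits: Mapping[str, LogisticFit],
    cutoff: float | None = None,
) -> EvaluationReport:
    """Score labeled records with the branch-appropriate model.

    ``fits`` maps branch name ("optimum", "non_optimum") to the fitted model
    for that branch; a branch with records present but no fit is an error,
    as is a record with no homology status.  Records incomplete for their
    branch's model (or unlabeled) are excluded and counted.
    """
    labeled = [r for r in records if r.label is not None]
    if not labeled:
        raise EvaluationError("no labeled records to evaluate")

    by_branch: dict[str, list[ResidueRecord]] = {OPTIMUM: [], NON_OPTIMUM: []}
    for rec in labeled:
        if rec.homology_status not in by_branch:
            raise EvaluationError(
                f"{rec.chain_id}:{rec.position}: unknown homology branch "
                f"{rec.homology_status!r}"
            )
        by_branch[rec.homology_status].append(rec)

    scored: list[tuple[ResidueRecord, int]] = []
    n_excluded = 0
    branch_counts: dict[str, tuple[int, float]] = {}
    models: dict[str, str] = {}
    for branch, branch_records in by_branch.items():
        if not branch_records:
            continue
        fit = fits.get(branch)
        if fit is None:
            raise EvaluationError(
                f"{len(branch_records)} record(s) on the {branch} branch "
                f"but no model supplied for it"
            )
        usable = complete_records(branch_records, fit.spec, require_label=True)
        n_excluded += len(branch_records) - len(usable)
        if not usable:
            continue
        eff_cutoff = cutoff if cutoff is not None else fit.spec.classification_cutoff
        pred = classify(predict_proba(fit, usable), eff_cutoff)
        for rec, cls in zip(usable, pred):
            scored.append((rec, int(cls)))
        branch_counts[branch] = (
            len(usable),
            accuracy(pred, [r.label for r in usable]),
        )
        models[branch] = fit.spec.name or "+".join(fit.spec.descriptors)

    if not scored:
        raise EvaluationError("no scorable records after exclusions")

    def _stratum(records_preds: list[tuple[ResidueRecord, int]]) -> StratumResult:
        preds = [p for _, p in records_preds]
        labs = [r.label for r, _ in records_preds]
        return StratumResult(len(records_preds), accuracy(preds, labs))

    strata: dict[str, StratumResult] = {"all": _stratum(scored)}
    for branch, (n, acc) in branch_counts.items():
        strata[branch] = StratumResult(n, acc)

    oligo = [(r, p) for r, p in scored if r.oligomer is True]
    non_oligo = [(r, p) for r, p in scored if r.oligomer is False]
    if oligo:
        strata["oligomer"] = _stratum(oligo)
        no_iface = [(r, p) for r, p in oligo if r.interfacial is not True]
        iface = [(r, p) for r, p in oligo if r.interfacial is True]
        if no_iface:
            strata["oligomer_without_interface"] = _stratum(no_iface)
        if iface:
            strata["interfacial_only"] = _stratum(iface)
    if non_oligo:
        strata["non_oligomer"] = _stratum(non_oligo)

    delta_codes: dict[str, str] = {}
    if "oligomer" in strata and "non_oligomer" in strata:
        delta_codes["oligomer_minus_non_oligomer"] = delta_code(
            strata["oligomer"].accuracy - strata["non_oligomer"].accuracy
        )
    if "oligomer_without_interface" in strata and "oligomer" in strata:
        delta_codes["interface_removed_minus_oligomer"] = delta_code(
            strata["oligomer_without_interface"].accuracy
            - strata["oligomer"].accuracy
        )

    weighted = weighted_accuracy(list(branch_counts.values()))

    some_fit = next(iter(fits.values()))
    eff_cutoff = cutoff if cutoff is not None else some_fit.spec.classification_cutoff
    return EvaluationReport(
        strata=strata,
        weighted_all_proteins=weighted,
        delta_codes=delta_codes,
        models=models,
        rsa_threshold=some_fit.spec.rsa_threshold,
        classification_cutoff=eff_cutoff,
        n_excluded=n_excluded,
    )
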