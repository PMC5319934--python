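"""Recovery and enrichment metrics for target-prediction benchmarks.

Given a prediction report and the set of known targets of the query, the
recovery metrics are

    fraction_known_found = |known ∩ predicted| / |known|
    hit_rate             = |known ∩ predicted| / |predicted|   (0 if none)
    top5 success         = any known target among the first 5 consensus ranks

computed per fingerprint space, for the combined (votes >= 2) list, and
stratified by p-value at 0.01.  Enrichment metrics (ROC AUC and enrichment
factor) evaluate a distance-ranked actives-vs-decoys screen, the standard
way of comparing fingerprints on retrieval benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .chem_fingerprints import ALL_SCHEMES, Scheme
from .distance_fusion import ScalingTable
from .predictor import (
    HIGH_CONFIDENCE_P,
    PredictionReport,
    TargetHit,
    predict,
)
from .pvalue_calibration import CalibrationSet
from .reference_db import ReferenceDatabase
from .chem_fingerprints import standardize

logger = logging.getLogger("ppb")


@dataclass(frozen=True)
class ListMetrics:
    """Recovery numbers for one predicted-target list."""

    n_predicted: int
    n_known_found: int
    fraction_known_found: float
    hit_rate: float


@dataclass
class RecoveryMetrics:
    """Recovery of a drug's known targets across all prediction lists."""

    drug_id: str
    n_known: int
    per_scheme: dict[Scheme, ListMetrics]
    combined: ListMetrics
    top5_success: bool
    #: p-stratified variants keyed (scheme or "combined", "low_p"/"high_p")
    stratified: dict[tuple[str, str], ListMetrics] = field(default_factory=dict)


def _list_metrics(predicted: Sequence[str], known: set[str]) -> ListMetrics:
    pset = set(predicted)
    found = len(pset & known)
    return ListMetrics(
        n_predicted=len(pset),
        n_known_found=found,
        fraction_known_found=found / len(known) if known else 0.0,
        hit_rate=found / len(pset) if pset else 0.0,
    )


def _stratify(hits: Sequence[TargetHit]) -> tuple[list[str], list[str]]:
    """Split a hit list at p <= 0.01; hits without a p go to the high-p side."""
    low = [h.target_id for h in hits if h.p is not None and h.p <= HIGH_CONFIDENCE_P]
    high = [h.target_id for h in hits if h.p is None or h.p > HIGH_CONFIDENCE_P]
    return low, high


def evaluate_recovery(
    report: PredictionReport, known: set[str], min_votes: int = 2, topk: int = 5
) -> RecoveryMetrics:
    """Recovery metrics for one prediction against the known-target set."""
    if not known:
        raise ValueError("empty known-target set")
    per_scheme: dict[Scheme, ListMetrics] = {}
    stratified: dict[tuple[str, str], ListMetrics] = {}
    for scheme, hits in report.per_scheme.items():
        per_scheme[scheme] = _list_metrics([h.target_id for h in hits], known)
        low, high = _stratify(hits)
        stratified[(str(scheme), "low_p")] = _list_metrics(low, known)
        stratified[(str(scheme), "high_p")] = _list_metrics(high, known)
    combined_entries = report.combined(min_votes)
    combined = _list_metrics([e.target_id for e in combined_entries], known)
    low_c = [e.target_id for e in combined_entries if e.best_p <= HIGH_CONFIDENCE_P]
    high_c = [e.target_id for e in combined_entries if e.best_p > HIGH_CONFIDENCE_P]
    stratified[("combined", "low_p")] = _list_metrics(low_c, known)
    stratified[("combined", "high_p")] = _list_metrics(high_c, known)
    return RecoveryMetrics(
        drug_id=report.query_id,
        n_known=len(known),
        per_scheme=per_scheme,
        combined=combined,
        top5_success=topk_success(report, known, k=topk),
        stratified=stratified,
    )


def topk_success(report: PredictionReport, known: set[str], k: int = 5) -> bool:
    """True iff any of the first ``k`` consensus targets is known."""
    return any(e.target_id in known for e in report.consensus[:k])


def overlap_stats(
    per_scheme_targets: Mapping[Scheme, set[str]]
) -> tuple[pd.DataFrame, dict[Scheme, float]]:
    """Pairwise target overlap between fingerprints and per-scheme uniqueness.

    overlap(i, j) = |T_i ∩ T_j| / |T_i| (row-normalized, hence asymmetric);
    unique(i) = fraction of T_i found by no other scheme.  Empty sets yield
    zero rows with a warning.
    """
    schemes = list(per_scheme_targets)
    if len(schemes) < 2:
        raise ValueError("need at least 2 schemes for overlap statistics")
    mat = pd.DataFrame(0.0, index=[str(s) for s in schemes], columns=[str(s) for s in schemes])
    unique: dict[Scheme, float] = {}
    for si in schemes:
        ti = per_scheme_targets[si]
        if not ti:
            logger.warning("overlap_stats: empty target set for %s", si)
            unique[si] = 0.0
            continue
        others = set().union(*(per_scheme_targets[sj] for sj in schemes if sj != si))
        unique[si] = len(ti - others) / len(ti)
        for sj in schemes:
            mat.loc[str(si), str(sj)] = len(ti & per_scheme_targets[sj]) / len(ti)
    return mat, unique


# ---------------------------------------------------------------------------
# enrichment metrics
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[tuple[float, bool]]) -> float:
    """Area under the ROC curve by the rank statistic with tie correction.

    ``scores`` are (score, is_active) with larger scores ranked better (pass
    negated distances for a distance-ranked screen).  Equals the
    Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    y = np.array([bool(a) for _, a in scores])
    s = np.array([float(v) for v, _ in scores])
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both actives and inactives")
    ranks = _sstats.rankdata(s)  # midranks handle ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def enrichment_factor(scores: Sequence[tuple[float, bool]], frac: float = 0.01) -> float:
    """Enrichment factor at the top ``frac`` of the ranked screen.

    EF = (fraction of all actives found in the top frac) / frac, equivalently
    the active concentration in the top slice relative to the whole screen.
    Ties at the cutoff are resolved by the deterministic (score desc, input
    order) ranking.
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"frac must be in (0,1], got {frac}")
    y = [bool(a) for _, a in scores]
    s = [float(v) for v, _ in scores]
    n = len(y)
    n_act = sum(y)
    if n_act == 0 or n_act == n:
        raise ValueError("enrichment_factor needs both actives and inactives")
    order = sorted(range(n), key=lambda i: (-s[i], i))
    n_top = max(1, int(round(frac * n)))
    found = sum(1 for i in order[:n_top] if y[i])
    return (found / n_act) / (n_top / n)


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkResult:
    per_drug: list[RecoveryMetrics]
    summary: pd.DataFrame

    def per_drug_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.per_drug:
            row: dict = {
                "drug_id": m.drug_id,
                "n_known": m.n_known,
                "top5_success": m.top5_success,
                "combined_fraction_known_found": m.combined.fraction_known_found,
                "combined_n_predicted": m.combined.n_predicted,
                "combined_hit_rate": m.combined.hit_rate,
            }
            for scheme, lm in m.per_scheme.items():
                row[f"{scheme}_fraction_known_found"] = lm.fraction_known_found
                row[f"{scheme}_n_predicted"] = lm.n_predicted
                row[f"{scheme}_hit_rate"] = lm.hit_rate
            rows.append(row)
        return pd.DataFrame(rows)


def benchmark_run(
    db: ReferenceDatabase,
    calib: CalibrationSet | None,
    st: ScalingTable,
    drugs: Sequence[tuple[str, str, set[str]]],
    n_targets: int = 20,
    min_votes: int = 2,
    schemes: Sequence[Scheme] | None = None,
    remove_drugs: bool = True,
) -> BenchmarkResult:
    """Leave-out benchmark over a drug panel.

    ``drugs`` is a list of (drug_id, smiles, known target ids).  Each drug's
    structure is removed from the reference database before it is queried;
    with ``remove_drugs=False`` a drug found verbatim in the database raises,
    preventing silently optimistic self-retrieval.
    """
    if schemes is None:
        schemes = ALL_SCHEMES
    canon = {did: standardize(smi).canonical_smiles for did, smi, _ in drugs}
    member_smiles = {smi for g in db.groups for _, smi in g.members}
    if remove_drugs:
        search_db = db.without_compounds(canon.values())
    else:
        present = [did for did, smi in canon.items() if smi in member_smiles]
        if present:
            raise ValueError(
                f"benchmark drugs present in database with removal disabled: {present}"
            )
        search_db = db
    per_drug: list[RecoveryMetrics] = []
    for drug_id, smiles, known in drugs:
        report = predict(
            smiles, search_db, calib=calib, st=st,
            n_targets=n_targets, schemes=schemes, query_id=drug_id,
        )
        per_drug.append(evaluate_recovery(report, set(known), min_votes=min_votes))

    rows = []
    for scheme in schemes:
        vals = [m.per_scheme[scheme] for m in per_drug if scheme in m.per_scheme]
        rows.append(
            {
                "method": str(scheme),
                "mean_fraction_known_found": float(
                    np.mean([v.fraction_known_found for v in vals])
                ),
                "mean_n_predicted": float(np.mean([v.n_predicted for v in vals])),
                "mean_hit_rate": float(np.mean([v.hit_rate for v in vals])),
            }
        )
    rows.append(
        {
            "method": "combined",
            "mean_fraction_known_found": float(
                np.mean([m.combined.fraction_known_found for m in per_drug])
            ),
            "mean_n_predicted": float(np.mean([m.combined.n_predicted for m in per_drug])),
            "mean_hit_rate": float(np.mean([m.combined.hit_rate for m in per_drug])),
        }
    )
    summary = pd.DataFrame(rows)
    summary["top5_success_rate"] = float(np.mean([m.top5_success for m in per_drug]))
    return BenchmarkResult(per_drug=per_drug, summary=summary)
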