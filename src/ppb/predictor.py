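"""Multi-fingerprint nearest-neighbor target prediction.

For a query molecule the engine sorts every reference compound by city-block
distance in each of the ten fingerprint spaces independently, walks each
sorted list collecting the first ``n_targets`` distinct targets (each scored
by its nearest member and that distance's null p-value), and merges the ten
per-fingerprint target lists into a consensus ranking:

    1. votes (number of fingerprint spaces that retrieved the target), desc
    2. sum of p-values over the voting spaces, asc
    3. best (smallest) p-value, asc
    4. target id, asc  (determinism)

The *combined* prediction keeps only targets voted by at least two
fingerprints.  A p-value <= 0.01 marks a high-confidence hit; a distance of
exactly 0 flags that the identical structure is present in the reference set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem_fingerprints import (
    ALL_SCHEMES,
    FingerprintProfile,
    Scheme,
    compute_profile,
    standardize,
)
from .distance_fusion import ScalingTable, profile_distance
from .pvalue_calibration import CalibrationSet
from .reference_db import ReferenceDatabase

logger = logging.getLogger("ppb")

DEFAULT_N_TARGETS = 20
HIGH_CONFIDENCE_P = 0.01


@dataclass(frozen=True)
class TargetHit:
    """One target retrieved in one fingerprint space."""

    target_id: str
    scheme: Scheme
    nn_distance: float
    nn_compound_id: str
    p: float | None = None

    @property
    def identical_flag(self) -> bool:
        """The reference set contains the query structure itself."""
        return self.nn_distance == 0

    @property
    def high_confidence(self) -> bool:
        return self.p is not None and self.p <= HIGH_CONFIDENCE_P


@dataclass(frozen=True)
class ConsensusEntry:
    target_id: str
    votes: int
    p_sum: float
    best_p: float
    rank: int


@dataclass
class PredictionReport:
    """Per-fingerprint hit lists plus the merged consensus ranking."""

    query_id: str
    query_smiles: str
    per_scheme: dict[Scheme, list[TargetHit]]
    consensus: list[ConsensusEntry]
    options: dict = field(default_factory=dict)

    def combined(self, min_votes: int = 2) -> list[ConsensusEntry]:
        """Consensus entries voted by at least ``min_votes`` fingerprints."""
        return [e for e in self.consensus if e.votes >= min_votes]

    def targets(self, scheme: Scheme) -> list[str]:
        return [h.target_id for h in self.per_scheme.get(scheme, [])]

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "query_smiles": self.query_smiles,
            "options": self.options,
            "per_scheme": {
                str(s): [
                    {
                        "target_id": h.target_id,
                        "nn_distance": h.nn_distance,
                        "nn_compound_id": h.nn_compound_id,
                        "p": h.p,
                        "identical": h.identical_flag,
                        "high_confidence": h.high_confidence,
                    }
                    for h in hits
                ]
                for s, hits in self.per_scheme.items()
            },
            "consensus": [
                {
                    "rank": e.rank,
                    "target_id": e.target_id,
                    "votes": e.votes,
                    "p_sum": e.p_sum,
                    "best_p": e.best_p,
                }
                for e in self.consensus
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def format_table(self, min_votes: int = 1, max_rows: int = 30) -> str:
        """Human-readable consensus table."""
        lines = [
            f"query: {self.query_id}  {self.query_smiles}",
            f"{'rank':>4} {'target':<24} {'votes':>5} {'p_sum':>10} {'best_p':>10}",
        ]
        for e in self.consensus[:max_rows]:
            if e.votes < min_votes:
                continue
            lines.append(
                f"{e.rank:>4} {e.target_id:<24} {e.votes:>5} {e.p_sum:>10.4g} {e.best_p:>10.4g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def rank_neighbors(
    query: FingerprintProfile,
    db: ReferenceDatabase,
    scheme: Scheme,
    st: ScalingTable,
) -> list[tuple[str, float]]:
    """All reference compounds sorted by ascending distance to the query.

    Ties are broken lexicographically by compound id so the ordering is
    deterministic regardless of database insertion order.
    """
    if not db.profiles:
        raise ValueError("empty reference database")
    dists = [
        (cid, profile_distance(query, prof, scheme, st))
        for cid, prof in db.profiles.items()
    ]
    dists.sort(key=lambda t: (t[1], t[0]))
    return [(cid, d) for cid, d in dists]


def collect_targets(
    ordered: Sequence[tuple[str, float]],
    db: ReferenceDatabase,
    scheme: Scheme,
    n_targets: int = DEFAULT_N_TARGETS,
    calib: CalibrationSet | None = None,
) -> list[TargetHit]:
    """Scan the neighbor list and keep the first ``n_targets`` distinct
    targets; each hit records the nearest member found for that target and
    the p-value of its distance."""
    compound_targets = db.compound_targets()
    hits: list[TargetHit] = []
    seen: set[str] = set()
    for cid, dist in ordered:
        for target_id in compound_targets.get(cid, ()):
            if target_id in seen:
                continue
            p = calib.p_value(target_id, scheme, dist) if calib is not None else None
            hits.append(
                TargetHit(
                    target_id=target_id,
                    scheme=scheme,
                    nn_distance=dist,
                    nn_compound_id=cid,
                    p=p,
                )
            )
            seen.add(target_id)
            if len(seen) >= n_targets:
                return hits
    return hits


def merge_consensus(
    per_scheme_hits: Mapping[Scheme, Sequence[TargetHit]],
    query_id: str = "",
    query_smiles: str = "",
    options: dict | None = None,
) -> PredictionReport:
    """Merge per-fingerprint hit lists into the consensus ranking.

    Votes count the schemes listing a target; p_sum adds the p-values over
    voting schemes (a missing/uncalibrated p contributes 1.0, ranking it
    below calibrated ties).
    """
    if not per_scheme_hits:
        raise ValueError("no per-scheme hit lists to merge")
    stats: dict[str, dict] = {}
    for scheme, hits in per_scheme_hits.items():
        for h in hits:
            s = stats.setdefault(h.target_id, {"votes": 0, "p_sum": 0.0, "best_p": 1.0})
            s["votes"] += 1
            p_eff = 1.0 if h.p is None else h.p
            s["p_sum"] += p_eff
            s["best_p"] = min(s["best_p"], p_eff)
    order = sorted(
        stats.items(), key=lambda kv: (-kv[1]["votes"], kv[1]["p_sum"], kv[1]["best_p"], kv[0])
    )
    consensus = [
        ConsensusEntry(
            target_id=tid, votes=s["votes"], p_sum=s["p_sum"], best_p=s["best_p"], rank=r
        )
        for r, (tid, s) in enumerate(order, 1)
    ]
    return PredictionReport(
        query_id=query_id,
        query_smiles=query_smiles,
        per_scheme={s: list(h) for s, h in per_scheme_hits.items()},
        consensus=consensus,
        options=options or {},
    )


def predict(
    smiles: str,
    db: ReferenceDatabase,
    calib: CalibrationSet | None = None,
    st: ScalingTable | None = None,
    n_targets: int = DEFAULT_N_TARGETS,
    schemes: Sequence[Scheme] | None = None,
    query_id: str = "query",
) -> PredictionReport:
    """Full prediction pipeline for one query SMILES.

    standardize -> profile -> per-scheme neighbor ranking and target
    collection -> consensus merge.  Deterministic for a fixed database,
    scaling table and calibration set.
    """
    if st is None:
        st = ScalingTable.identity()
    if schemes is None:
        schemes = ALL_SCHEMES
    if calib is None:
        logger.warning("predict: no calibration set; p-values will be null")
    mol = standardize(smiles, mol_id=query_id)
    profile = compute_profile(mol)
    per_scheme: dict[Scheme, list[TargetHit]] = {}
    for scheme in schemes:
        ordered = rank_neighbors(profile, db, scheme, st)
        per_scheme[scheme] = collect_targets(
            ordered, db, scheme, n_targets=n_targets, calib=calib
        )
    return merge_consensus(
        per_scheme,
        query_id=query_id,
        query_smiles=mol.canonical_smiles,
        options={"n_targets": n_targets, "schemes": [str(s) for s in schemes]},
    )
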