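"""Negative-binomial null models for query-group distances.

A target prediction is scored by the city-block distance between the query
and the nearest member of the target's compound group.  To judge how likely
such a distance is to arise by chance, a null distance distribution is built
per (target, fingerprint space) by measuring distances between the group's
members and random background molecules.  Each empirical distribution is
fitted with a negative binomial — a natural choice given the discrete,
overdispersed nature of city-block distances — and the fitted CDF converts
an observed nearest-neighbor distance d into

    p = P(D <= d)

the probability that a random molecule lies at least as close to the group.
The p-value is specific to its (target, fingerprint) pair and is never
compared across targets or fingerprint spaces; the ranking layer uses it
only within targets (sums and thresholds).

Parametrization follows the usual (size r, prob p) convention with
pmf(k) = C(k+r-1, k) p^r (1-p)^k, mean r(1-p)/p.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .chem_fingerprints import FingerprintProfile, Molecule, Scheme, compute_profiles
from .distance_fusion import ScalingTable, profile_distance
from .reference_db import ReferenceDatabase, TargetGroup

logger = logging.getLogger("ppb")

DEFAULT_MAX_PAIRS = 1_000_000
MIN_FIT_SAMPLES = 100
FIT_TOL = 1e-8


class FitDegeneracyError(ValueError):
    """Raised when an NB maximum-likelihood fit is ill-posed (constant or
    underdispersed sample); callers should fall back to a Poisson fit."""


@dataclass(frozen=True)
class NBParams:
    """Fitted negative-binomial null parameters for one (target, scheme)."""

    size_r: float
    prob_p: float
    n_samples: int = 0
    fit_loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.size_r > 0):
            raise ValueError(f"size_r must be positive, got {self.size_r}")
        if not (0.0 < self.prob_p < 1.0):
            raise ValueError(f"prob_p must be in (0,1), got {self.prob_p}")


@dataclass(frozen=True)
class PoissonParams:
    """Poisson fallback null for underdispersed distance samples."""

    mu: float
    n_samples: int = 0


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------


def sample_background_distances(
    group: TargetGroup,
    background: Sequence[FingerprintProfile],
    scheme: Scheme,
    st: ScalingTable,
    db_profiles: Mapping[str, FingerprintProfile],
    n_max: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> np.ndarray:
    """Member-background distances under one scheme, rounded to integers.

    All member x background pairs are used when there are at most ``n_max``
    of them; otherwise ``n_max`` pairs are drawn uniformly with a seeded
    generator.  Scaled/fused distances are rounded to the nearest integer to
    preserve the discreteness the negative binomial requires.
    """
    if len(group) == 0:
        raise ValueError(f"empty group {group.target_id}")
    if len(background) == 0:
        raise ValueError("empty background set")
    members = [db_profiles[cid] for cid in group.compound_ids]
    n_total = len(members) * len(background)
    if n_total <= n_max:
        pairs = [(i, j) for i in range(len(members)) for j in range(len(background))]
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, len(members), size=n_max)
        jj = rng.integers(0, len(background), size=n_max)
        pairs = list(zip(ii, jj))
    dists = np.fromiter(
        (
            round(profile_distance(members[i], background[j], scheme, st))
            for i, j in pairs
        ),
        dtype=np.int64,
        count=len(pairs),
    )
    return dists


# ---------------------------------------------------------------------------
# negative-binomial fitting
# ---------------------------------------------------------------------------


def _nb_method_of_moments(samples: np.ndarray) -> tuple[float, float]:
    """(size_r, prob_p) from sample mean/variance; requires var > mean."""
    mean = float(samples.mean())
    var = float(samples.var(ddof=1))
    r = mean * mean / (var - mean)
    p = mean / var
    return r, p


def nb_log_likelihood(samples: np.ndarray, size_r: float, prob_p: float) -> float:
    """Negative-binomial log-likelihood via the gamma-function pmf."""
    k = samples.astype(np.float64)
    return float(
        np.sum(
            special.gammaln(k + size_r)
            - special.gammaln(size_r)
            - special.gammaln(k + 1)
            + size_r * math.log(prob_p)
            + k * np.log1p(-prob_p)
        )
    )


def fit_negative_binomial(samples: Sequence[int]) -> NBParams:
    """Maximum-likelihood negative-binomial fit of a discrete sample.

    Optimizes over (log size_r, logit prob_p), initialized at the
    method-of-moments estimate.  Raises :class:`FitDegeneracyError` for
    constant or underdispersed samples (variance <= mean), where the NB MLE
    diverges toward a Poisson.
    """
    x = np.asarray(samples, dtype=np.int64)
    if x.size < MIN_FIT_SAMPLES:
        raise ValueError(f"need >= {MIN_FIT_SAMPLES} samples, got {x.size}")
    if (x < 0).any():
        raise ValueError("negative values in sample")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var <= mean or mean == 0.0:
        raise FitDegeneracyError(
            f"sample variance {var:.4g} <= mean {mean:.4g}: "
            "negative-binomial MLE is degenerate, fall back to Poisson"
        )
    r0, p0 = _nb_method_of_moments(x)

    # aggregate by unique value: the sample is discrete with few distinct
    # levels, so this makes each objective evaluation O(#levels)
    values, counts = np.unique(x, return_counts=True)
    values_f = values.astype(np.float64)
    weights = counts.astype(np.float64)
    n = float(x.size)
    total = float(x.sum())

    def neg_loglik(theta: np.ndarray) -> float:
        r = math.exp(theta[0])
        p = special.expit(theta[1])
        ll = (
            float(np.sum(weights * (special.gammaln(values_f + r) - special.gammaln(values_f + 1))))
            - n * special.gammaln(r)
            + n * r * math.log(p)
            + total * math.log1p(-p)
        )
        return -ll

    theta0 = np.array([math.log(r0), special.logit(p0)])
    res = optimize.minimize(
        neg_loglik, theta0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": FIT_TOL, "maxiter": 2000},
    )
    r_hat = math.exp(res.x[0])
    p_hat = float(special.expit(res.x[1]))
    return NBParams(
        size_r=r_hat, prob_p=p_hat, n_samples=int(x.size), fit_loglik=float(-res.fun)
    )


def fit_poisson(samples: Sequence[int]) -> PoissonParams:
    """Poisson MLE (sample mean) used as the underdispersed fallback."""
    x = np.asarray(samples, dtype=np.int64)
    if x.size == 0:
        raise ValueError("empty sample")
    return PoissonParams(mu=float(x.mean()), n_samples=int(x.size))


def p_value(params: NBParams | PoissonParams, distance: float) -> float:
    """P(D <= round(distance)) under the fitted null.

    The probability that a random query-group distance is at least as small
    as the observed one; non-decreasing in the distance.
    """
    if distance < 0:
        raise ValueError(f"negative distance: {distance}")
    k = int(round(distance))
    if isinstance(params, NBParams):
        return float(stats.nbinom.cdf(k, params.size_r, params.prob_p))
    return float(stats.poisson.cdf(k, params.mu))


# ---------------------------------------------------------------------------
# whole-database calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationEntry:
    target_id: str
    scheme: Scheme
    status: str  # "nb" | "poisson" | "degenerate"
    params: NBParams | PoissonParams | None


@dataclass
class CalibrationSet:
    """Fitted null parameters per (target, scheme) pair."""

    entries: dict[tuple[str, Scheme], CalibrationEntry]
    background_description: str = ""
    seed: int = 0

    def lookup(self, target_id: str, scheme: Scheme) -> CalibrationEntry | None:
        return self.entries.get((target_id, scheme))

    def p_value(self, target_id: str, scheme: Scheme, distance: float) -> float | None:
        """p for an observed distance, or None when no usable fit exists."""
        entry = self.lookup(target_id, scheme)
        if entry is None or entry.params is None:
            return None
        return p_value(entry.params, distance)

    @property
    def n_failed(self) -> int:
        return sum(1 for e in self.entries.values() if e.params is None)

    def to_json(self, path: str) -> None:
        rows = []
        for (tid, scheme), e in sorted(self.entries.items()):
            row: dict = {"target_id": tid, "scheme": str(scheme), "status": e.status}
            if isinstance(e.params, NBParams):
                row.update(
                    size_r=e.params.size_r, prob_p=e.params.prob_p,
                    n_samples=e.params.n_samples, fit_loglik=e.params.fit_loglik,
                )
            elif isinstance(e.params, PoissonParams):
                row.update(mu=e.params.mu, n_samples=e.params.n_samples)
            rows.append(row)
        payload = {
            "background": self.background_description,
            "seed": self.seed,
            "entries": rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CalibrationSet":
        with open(path) as fh:
            payload = json.load(fh)
        entries: dict[tuple[str, Scheme], CalibrationEntry] = {}
        for row in payload["entries"]:
            scheme = Scheme(row["scheme"])
            status = row["status"]
            params: NBParams | PoissonParams | None
            if status == "nb":
                params = NBParams(
                    size_r=row["size_r"], prob_p=row["prob_p"],
                    n_samples=row["n_samples"], fit_loglik=row.get("fit_loglik", float("nan")),
                )
            elif status == "poisson":
                params = PoissonParams(mu=row["mu"], n_samples=row["n_samples"])
            else:
                params = None
            entries[(row["target_id"], scheme)] = CalibrationEntry(
                target_id=row["target_id"], scheme=scheme, status=status, params=params
            )
        return cls(
            entries=entries,
            background_description=payload.get("background", ""),
            seed=payload.get("seed", 0),
        )


def calibrate_database(
    db: ReferenceDatabase,
    background: Sequence[Molecule],
    st: ScalingTable,
    schemes: Sequence[Scheme] | None = None,
    n_max: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> CalibrationSet:
    """Fit one null distribution per (target group, scheme).

    Groups whose NB fit degenerates fall back to a Poisson fit; samples that
    are constant are recorded as ``degenerate`` entries and excluded from
    p-value ranking (distance-only fallback downstream).  Individual failures
    never abort the whole calibration.
    """
    from .chem_fingerprints import ALL_SCHEMES

    if schemes is None:
        schemes = ALL_SCHEMES
    member_smiles = {smi for g in db.groups for _, smi in g.members}
    overlap = sum(1 for m in background if m.canonical_smiles in member_smiles)
    if overlap:
        logger.warning(
            "calibrate_database: %d background molecules are database members", overlap
        )
    bg_profiles = compute_profiles(background)
    entries: dict[tuple[str, Scheme], CalibrationEntry] = {}
    for gi, group in enumerate(db.groups):
        for si, scheme in enumerate(schemes):
            pair_seed = (seed + 1009 * gi + 31 * si) % (2**31)
            samples = sample_background_distances(
                group, bg_profiles, scheme, st, db.profiles, n_max=n_max, seed=pair_seed
            )
            key = (group.target_id, scheme)
            try:
                params: NBParams | PoissonParams | None = fit_negative_binomial(samples)
                status = "nb"
            except FitDegeneracyError:
                if samples.var(ddof=1) > 0:
                    params = fit_poisson(samples)
                    status = "poisson"
                else:
                    params, status = None, "degenerate"
                logger.warning(
                    "calibration %s/%s: %s fallback", group.target_id, scheme, status
                )
            except ValueError as exc:
                params, status = None, "degenerate"
                logger.warning("calibration %s/%s failed: %s", group.target_id, scheme, exc)
            entries[key] = CalibrationEntry(
                target_id=group.target_id, scheme=scheme, status=status, params=params
            )
    return CalibrationSet(
        entries=entries,
        background_description=f"{len(background)} background molecules",
        seed=seed,
    )
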