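"""City-block distance, mode-matched fingerprint scaling, and fused fingerprints.

All similarity in the engine is the city-block (Manhattan) distance

    CBD(A, B) = sum_j |A_j - B_j|

over fingerprint vectors.  Because the six base schemes live on very
different scales (a 21-D shape histogram vs. a 1024-bit substructure
fingerprint), fingerprints are made commensurate before fusion by *mode
matching*: the distance distribution of random molecule pairs is computed in
each fingerprint space and every scheme is rescaled so its most frequent
random-pair distance equals that of the reference scheme Xfp.  A fused
fingerprint distance is then the scale-weighted sum of its components'
distances — identical, by linearity, to the CBD of the scaled concatenated
vectors.

Four fused schemes are defined:

    Ffp1 = Xfp + SMIfp + Sfp
    Ffp2 = Xfp + MQN + SMIfp
    Ffp3 = Xfp + SMIfp + Sfp + ECfp4
    Ffp4 = Xfp + MQN + SMIfp + Sfp + ECfp4
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chem_fingerprints import (
    BASE_SCHEMES,
    FingerprintProfile,
    FingerprintVector,
    Molecule,
    Scheme,
    compute_profiles,
)

#: default number of random pairs for production scaling calibration
DEFAULT_SCALING_PAIRS = 50_000_000


class CalibrationError(ValueError):
    """Raised when scaling calibration degenerates (e.g. zero-mode sample)."""


@dataclass(frozen=True)
class FfpDefinition:
    name: Scheme
    components: tuple[Scheme, ...]


FFP_DEFINITIONS: dict[Scheme, FfpDefinition] = {
    Scheme.Ffp1: FfpDefinition(Scheme.Ffp1, (Scheme.Xfp, Scheme.SMIfp, Scheme.Sfp)),
    Scheme.Ffp2: FfpDefinition(Scheme.Ffp2, (Scheme.Xfp, Scheme.MQN, Scheme.SMIfp)),
    Scheme.Ffp3: FfpDefinition(
        Scheme.Ffp3, (Scheme.Xfp, Scheme.SMIfp, Scheme.Sfp, Scheme.ECfp4)
    ),
    Scheme.Ffp4: FfpDefinition(
        Scheme.Ffp4, (Scheme.Xfp, Scheme.MQN, Scheme.SMIfp, Scheme.Sfp, Scheme.ECfp4)
    ),
}


def cbd(a: FingerprintVector, b: FingerprintVector) -> int:
    """City-block distance between two vectors of the same scheme."""
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    if len(a) != len(b):  # pragma: no cover - schemes fix dimensions
        raise ValueError(f"dimension mismatch: {len(a)} vs {len(b)}")
    return int(np.abs(a.values - b.values).sum())


def distance_mode(samples: Sequence[int]) -> int:
    """Most frequent distance in a sample; ties broken toward the smaller value."""
    if len(samples) == 0:
        raise ValueError("empty distance sample")
    counts = Counter(int(s) for s in samples)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


@dataclass(frozen=True)
class ScalingTable:
    """Per-scheme scale factors anchored to the Xfp distance mode.

    ``scale_factor[s] = mode(Xfp) / mode(s)`` so that after scaling every
    scheme's most frequent random-pair distance coincides with Xfp's.
    """

    mode_distance: Mapping[Scheme, int]
    scale_factor: Mapping[Scheme, float]
    sample_size: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for s in BASE_SCHEMES:
            if s not in self.scale_factor:
                raise ValueError(f"scaling table missing scheme {s}")
            if self.scale_factor[s] <= 0:
                raise ValueError(f"non-positive scale factor for {s}")
        if abs(self.scale_factor[Scheme.Xfp] - 1.0) > 1e-12:
            raise ValueError("Xfp scale factor must be exactly 1")

    @classmethod
    def identity(cls) -> "ScalingTable":
        """All-ones table (useful for unscaled comparisons and tests)."""
        return cls(
            mode_distance={s: 1 for s in BASE_SCHEMES},
            scale_factor={s: 1.0 for s in BASE_SCHEMES},
            sample_size=0,
        )

    def to_json(self, path: str) -> None:
        payload = {
            "reference_scheme": str(Scheme.Xfp),
            "sample_size": self.sample_size,
            "seed": self.seed,
            "schemes": {
                str(s): {
                    "mode_distance": int(self.mode_distance[s]),
                    "scale_factor": float(self.scale_factor[s]),
                }
                for s in BASE_SCHEMES
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ScalingTable":
        with open(path) as fh:
            payload = json.load(fh)
        modes = {
            Scheme(name): entry["mode_distance"]
            for name, entry in payload["schemes"].items()
        }
        factors = {
            Scheme(name): entry["scale_factor"]
            for name, entry in payload["schemes"].items()
        }
        return cls(
            mode_distance=modes,
            scale_factor=factors,
            sample_size=payload["sample_size"],
            seed=payload.get("seed"),
        )


def sample_pair_distances(
    profiles: Sequence[FingerprintProfile],
    scheme: Scheme,
    n_pairs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distances of ``n_pairs`` random (distinct-index) profile pairs."""
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least 2 profiles to sample pairs")
    ii = rng.integers(0, n, size=n_pairs)
    jj = rng.integers(0, n - 1, size=n_pairs)
    jj = np.where(jj >= ii, jj + 1, jj)  # avoid self-pairs
    return np.array(
        [cbd(profiles[i][scheme], profiles[j][scheme]) for i, j in zip(ii, jj)],
        dtype=np.int64,
    )


def scaling_from_distance_samples(
    samples: Mapping[Scheme, Sequence[int]],
    sample_size: int = 0,
    seed: int | None = None,
) -> ScalingTable:
    """Scaling table from per-scheme random-pair distance samples.

    Records each scheme's distance mode and sets
    ``scale_factor = mode(Xfp) / mode(scheme)``; a zero mode means the
    sample carries no scale information and raises :class:`CalibrationError`.
    """
    modes: dict[Scheme, int] = {}
    for scheme in BASE_SCHEMES:
        if scheme not in samples:
            raise ValueError(f"missing distance sample for scheme {scheme}")
        modes[scheme] = distance_mode(samples[scheme])
        if modes[scheme] == 0:
            raise CalibrationError(
                f"degenerate calibration: modal {scheme} distance is 0 "
                "(molecule set too uniform)"
            )
    ref = modes[Scheme.Xfp]
    factors = {s: ref / modes[s] for s in BASE_SCHEMES}
    factors[Scheme.Xfp] = 1.0
    return ScalingTable(
        mode_distance=modes, scale_factor=factors, sample_size=sample_size, seed=seed
    )


def calibrate_scaling(
    molecules: Sequence[Molecule], n_pairs: int = 100_000, seed: int = 0
) -> ScalingTable:
    """Estimate per-scheme distance modes from random molecule pairs and
    derive scale factors anchored to Xfp.

    The same seeded pair sample is reused across schemes so the table is a
    consistent snapshot of one random-pair population.
    """
    if len(molecules) < 2:
        raise ValueError("need at least 2 molecules for scaling calibration")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    profiles = compute_profiles(molecules)
    samples = {
        scheme: sample_pair_distances(
            profiles, scheme, n_pairs, np.random.default_rng(seed)
        )
        for scheme in BASE_SCHEMES
    }
    return scaling_from_distance_samples(samples, sample_size=n_pairs, seed=seed)


def base_distance(
    pa: FingerprintProfile, pb: FingerprintProfile, scheme: Scheme
) -> int:
    """Unscaled CBD between two profiles under one base scheme."""
    return cbd(pa[scheme], pb[scheme])


def fused_distance(
    pa: FingerprintProfile,
    pb: FingerprintProfile,
    ffp: FfpDefinition | Scheme,
    st: ScalingTable,
) -> float:
    """Scaled fused distance: sum over components of scale_factor x CBD.

    Equals the CBD of the scaled concatenated component vectors.
    """
    if isinstance(ffp, Scheme):
        if ffp not in FFP_DEFINITIONS:
            raise ValueError(f"unknown fused fingerprint: {ffp}")
        ffp = FFP_DEFINITIONS[ffp]
    return float(
        sum(st.scale_factor[c] * cbd(pa[c], pb[c]) for c in ffp.components)
    )


def profile_distance(
    pa: FingerprintProfile, pb: FingerprintProfile, scheme: Scheme, st: ScalingTable
) -> float:
    """Distance under any of the ten schemes: raw CBD for base schemes,
    scale-weighted component sum for fused schemes."""
    if scheme in FFP_DEFINITIONS:
        return fused_distance(pa, pb, scheme, st)
    return float(cbd(pa[scheme], pb[scheme]))
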