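"""Seeded generator of self-contained test worlds.

Real reference data for the prediction engine is a large bioactivity export;
for testing and examples this module fabricates a structurally coherent
miniature: each synthetic target is one drug-like scaffold from a bundled
library, its "actives" are combinatorial decorations of that scaffold with
small substituents, and queries are held-out decorations of the same
scaffold.  Because analogs share a scaffold while different targets use
different scaffolds, every query's nearest structural family is its true
target — a planted ground truth that the generator verifies exhaustively
(brute-force ECfp4 city-block nearest neighbor) before returning, so a
broken fixture can never be emitted silently.

Background/decoy molecules are decorations of scaffolds assigned to no
target.  Activity values are drawn log-uniformly between 1 nM and 10 uM; a
configurable fraction of deliberately failing rows (20 uM potency, 50%
inhibition) exercises the activity filters downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

from .chem_fingerprints import Scheme, compute_profile, standardize
from .distance_fusion import cbd

logger = logging.getLogger("ppb")

#: substituent branches used to decorate scaffold attachment sites
SUBSTITUENTS: tuple[str, ...] = (
    "", "(C)", "(F)", "(Cl)", "(Br)", "(O)", "(N)", "(OC)", "(C#N)", "(CC)",
    "(C(F)(F)F)",
)

ACTIVITY_TYPES = ("IC50", "EC50", "Ki", "KD")


class FixtureError(RuntimeError):
    """Raised when a fixture cannot satisfy its own ground-truth guarantees."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic test world."""

    seed: int = 0
    n_targets: int = 5
    group_size: int = 12
    n_background: int = 30
    n_queries_per_target: int = 3
    failing_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.group_size < 10:
            raise ValueError("group_size must be >= 10 to pass the retention filter")
        if self.n_targets < 1:
            raise ValueError("need at least 1 target")


@dataclass
class FixtureWorld:
    """A generated world: activity rows, background SMILES, annotated queries."""

    spec: FixtureSpec
    activity_rows: list[dict]
    background_smiles: list[str]
    queries: list[tuple[str, str, str]]  # (query_id, smiles, true target id)
    scaffold_names: dict[str, str] = field(default_factory=dict)

    def write_activity_tsv(self, path: str) -> None:
        cols = [
            "compound_id", "smiles", "target_id", "target_name", "target_type",
            "organism", "activity_type", "value", "unit",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.activity_rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    def write_background_smi(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, smi in enumerate(self.background_smiles):
                fh.write(f"{smi}\tBG{i + 1}\n")

    def write_queries_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tsmiles\ttrue_target\n")
            for qid, smi, target in self.queries:
                fh.write(f"{qid}\t{smi}\t{target}\n")


def load_scaffold_library() -> list[tuple[str, str]]:
    """Bundled (template, name) scaffold list; every template has two
    substitution sites."""
    text = resources.files("ppb.data").joinpath("scaffolds.smi").read_text()
    out: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        template, name = line.split("\t")
        out.append((template, name))
    return out


def _decorations(template: str, rng: np.random.Generator) -> list[str]:
    """All valid, structurally distinct decorations of a scaffold template,
    in seeded random order."""
    seen: set[str] = set()
    valid: list[str] = []
    for subs in itertools.product(SUBSTITUENTS, repeat=2):
        smi = template.format(*subs)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        valid.append(smi)
    order = rng.permutation(len(valid))
    return [valid[i] for i in order]


def _log_uniform_nm(rng: np.random.Generator) -> float:
    """Potency in nM, log-uniform between 1 nM and 10 uM."""
    return float(10 ** rng.uniform(0.0, 4.0))


def generate_fixture(spec: FixtureSpec) -> FixtureWorld:
    """Build a seeded test world satisfying the planted-ground-truth invariant.

    Raises :class:`FixtureError` when a scaffold cannot yield enough distinct
    decorations, or when the nearest-family self-check fails for every
    attempted scaffold-to-target assignment.
    """
    library = load_scaffold_library()
    needed = spec.group_size + spec.n_queries_per_target
    if spec.n_targets > len(library) - 1:
        raise FixtureError(
            f"{spec.n_targets} targets exceed the scaffold library "
            f"({len(library)} scaffolds, one reserved for background)"
        )
    for attempt in range(5):
        rng = np.random.default_rng((spec.seed + 7919 * attempt) % (2**31))
        order = rng.permutation(len(library))
        target_scaffolds = [library[i] for i in order[: spec.n_targets]]
        bg_scaffolds = [library[i] for i in order[spec.n_targets :]]
        try:
            world = _build_world(spec, rng, target_scaffolds, bg_scaffolds)
        except FixtureError as exc:
            logger.warning("fixture attempt %d failed self-check: %s", attempt, exc)
            continue
        return world
    raise FixtureError(
        "could not generate a fixture satisfying the nearest-family check; "
        "reduce group_size or enlarge the scaffold library"
    )


def _build_world(
    spec: FixtureSpec,
    rng: np.random.Generator,
    target_scaffolds: list[tuple[str, str]],
    bg_scaffolds: list[tuple[str, str]],
) -> FixtureWorld:
    needed = spec.group_size + spec.n_queries_per_target
    rows: list[dict] = []
    queries: list[tuple[str, str, str]] = []
    actives_by_target: dict[str, list[str]] = {}
    scaffold_names: dict[str, str] = {}
    n_failing = max(0, int(round(spec.failing_fraction * spec.group_size)))

    for t, (template, name) in enumerate(target_scaffolds, start=1):
        target_id = f"TGT{t}"
        scaffold_names[target_id] = name
        decs = _decorations(template, rng)
        if len(decs) < needed + n_failing:
            raise FixtureError(
                f"scaffold {name!r} yields only {len(decs)} distinct decorations, "
                f"need {needed + n_failing}"
            )
        members = decs[: spec.group_size]
        held_out = decs[spec.group_size : needed]
        failing = decs[needed : needed + n_failing]
        actives_by_target[target_id] = members
        for k, smi in enumerate(members, start=1):
            rows.append(
                {
                    "compound_id": f"T{t}C{k:03d}",
                    "smiles": smi,
                    "target_id": target_id,
                    "target_name": f"synthetic target {t} ({name})",
                    "target_type": "SINGLE PROTEIN",
                    "organism": "Homo sapiens",
                    "activity_type": ACTIVITY_TYPES[int(rng.integers(len(ACTIVITY_TYPES)))],
                    "value": round(_log_uniform_nm(rng), 3),
                    "unit": "nM",
                }
            )
        # deliberately failing rows: above the potency cutoff / at the
        # inhibition boundary, so filters have something to reject
        for k, smi in enumerate(failing, start=1):
            too_weak = bool(rng.integers(2))
            rows.append(
                {
                    "compound_id": f"T{t}F{k:03d}",
                    "smiles": smi,
                    "target_id": target_id,
                    "target_name": f"synthetic target {t} ({name})",
                    "target_type": "SINGLE PROTEIN",
                    "organism": "Homo sapiens",
                    "activity_type": "IC50" if too_weak else "PercentInhibition",
                    "value": 20000.0 if too_weak else 50.0,
                    "unit": "nM" if too_weak else "%",
                }
            )
        for q, smi in enumerate(held_out, start=1):
            queries.append((f"Q_T{t}_{q}", smi, target_id))

    background: list[str] = []
    bg_pool = []
    for template, _ in bg_scaffolds:
        bg_pool.extend(_decorations(template, rng))
    if len(bg_pool) < spec.n_background:
        raise FixtureError(
            f"background capacity {len(bg_pool)} < requested {spec.n_background}"
        )
    idx = rng.permutation(len(bg_pool))[: spec.n_background]
    background = [bg_pool[i] for i in sorted(idx)]

    world = FixtureWorld(
        spec=spec,
        activity_rows=rows,
        background_smiles=background,
        queries=queries,
        scaffold_names=scaffold_names,
    )
    _verify_nearest_family(world, actives_by_target)
    return world


def _verify_nearest_family(
    world: FixtureWorld, actives_by_target: dict[str, list[str]]
) -> None:
    """Exhaustive self-check: each query's brute-force ECfp4 CBD nearest
    neighbor among all actives must belong to its true target group."""
    fp_cache: dict[str, object] = {}

    def _fp(smiles: str):
        if smiles not in fp_cache:
            prof = compute_profile(standardize(smiles))
            fp_cache[smiles] = prof[Scheme.ECfp4]
        return fp_cache[smiles]

    for qid, smi, true_target in world.queries:
        qfp = _fp(smi)
        best_d, best_target = None, None
        for target_id, members in actives_by_target.items():
            for member in members:
                d = cbd(qfp, _fp(member))
                if best_d is None or d < best_d:
                    best_d, best_target = d, target_id
        if best_target != true_target:
            raise FixtureError(
                f"query {qid}: nearest active belongs to {best_target}, "
                f"expected {true_target} (distance {best_d})"
            )


def generate_nb_samples(size_r: float, prob_p: float, n: int, seed: int = 0) -> np.ndarray:
    """Seeded negative-binomial draws (oracle input for calibration tests)."""
    if size_r <= 0 or not (0.0 < prob_p < 1.0):
        raise ValueError(f"invalid NB parameters: size_r={size_r}, prob_p={prob_p}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.negative_binomial(size_r, prob_p, size=n).astype(np.int64)
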