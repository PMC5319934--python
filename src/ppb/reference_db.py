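"""Reference database construction from a ChEMBL-style activity table.

The database groups bioactive compounds by biological target.  A compound is
retained for a target when its recorded potency (IC50, EC50, GI50, Ki, KD or
Potency) is at most 10 uM after unit conversion, or its percent inhibition
exceeds 50%.  Structures are standardized (stereo-free, pH 7.4 ionization)
and deduplicated by canonical SMILES within each target; only targets with at
least 10 distinct actives are kept.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .chem_fingerprints import (
    ChemError,
    FingerprintProfile,
    Molecule,
    compute_profile,
    profiles_from_tsv,
    profiles_to_tsv,
    standardize,
)

logger = logging.getLogger("ppb")

DB_FORMAT_VERSION = 1

#: potency-type activities subject to the <=10 uM cutoff
POTENCY_TYPES = frozenset({"IC50", "EC50", "GI50", "Ki", "KD", "Potency"})
PERCENT_INHIBITION = "PercentInhibition"

POTENCY_CUTOFF_UM = 10.0
INHIBITION_CUTOFF_PCT = 50.0
DEFAULT_MIN_GROUP_SIZE = 10

#: unit -> factor converting a value to micromolar
_UNIT_TO_UM = {
    "nM": 1e-3,
    "uM": 1.0,
    "µM": 1.0,
    "mM": 1e3,
    "M": 1e6,
}

#: default column mapping for the supported activity-table dialect
DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "target_name": "target_name",
    "target_type": "target_type",
    "organism": "organism",
    "activity_type": "activity_type",
    "value": "value",
    "unit": "unit",
}

_ACTIVITY_ALIASES = {
    "ic50": "IC50",
    "ec50": "EC50",
    "gi50": "GI50",
    "ki": "Ki",
    "kd": "KD",
    "potency": "Potency",
    "percentinhibition": PERCENT_INHIBITION,
    "percent_inhibition": PERCENT_INHIBITION,
    "inhibition": PERCENT_INHIBITION,
}


class SchemaError(ValueError):
    """Raised when a mandatory activity-table column is missing."""


class DatabaseFormatError(ValueError):
    """Raised on database version mismatch or corrupted files."""


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    smiles: str
    target_id: str
    target_name: str = ""
    target_type: str = ""
    organism: str = ""
    activity_type: str = "IC50"
    value: float = float("nan")
    unit: str = "nM"


@dataclass(frozen=True)
class TargetGroup:
    """Deduplicated actives of one biological target."""

    target_id: str
    target_name: str = ""
    target_type: str = ""
    organism: str = ""
    #: (compound_id, canonical_smiles), canonical SMILES unique within group
    members: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.members)

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.members)


@dataclass
class ReferenceDatabase:
    """Target groups plus one fingerprint profile per unique compound."""

    groups: list[TargetGroup]
    profiles: dict[str, FingerprintProfile]  # keyed by compound_id
    canonical_smiles: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_compounds(self) -> int:
        return len(self.profiles)

    @property
    def target_ids(self) -> list[str]:
        return [g.target_id for g in self.groups]

    def group_by_id(self, target_id: str) -> TargetGroup:
        for g in self.groups:
            if g.target_id == target_id:
                return g
        raise KeyError(target_id)

    def compound_targets(self) -> dict[str, list[str]]:
        """compound_id -> sorted list of target ids it is active on."""
        out: dict[str, list[str]] = {}
        for g in self.groups:
            for cid, _ in g.members:
                out.setdefault(cid, []).append(g.target_id)
        return {cid: sorted(ts) for cid, ts in out.items()}

    def without_compounds(self, canonical_smiles: Iterable[str]) -> "ReferenceDatabase":
        """A view of the database with the given structures removed from every
        group (leave-out for benchmarking).  Group size is not re-filtered."""
        drop = set(canonical_smiles)
        new_groups = []
        removed = 0
        for g in self.groups:
            kept = tuple((cid, smi) for cid, smi in g.members if smi not in drop)
            removed += len(g.members) - len(kept)
            if kept:
                new_groups.append(replace(g, members=kept))
        kept_ids = {cid for g in new_groups for cid in g.compound_ids}
        return ReferenceDatabase(
            groups=new_groups,
            profiles={cid: p for cid, p in self.profiles.items() if cid in kept_ids},
            canonical_smiles={
                cid: s for cid, s in self.canonical_smiles.items() if cid in kept_ids
            },
            provenance={**self.provenance, "removed_members": removed},
        )


# ---------------------------------------------------------------------------
# loading and filtering
# ---------------------------------------------------------------------------


def _normalize_activity_type(raw: str) -> str:
    return _ACTIVITY_ALIASES.get(str(raw).strip().lower().replace(" ", ""), str(raw).strip())


def load_column_mapping(path: str) -> dict[str, str]:
    """Read a YAML column-mapping config ({field: column name})."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    return {**DEFAULT_COLUMNS, **(mapping or {})}


def load_activity_table(
    path: str, dialect: Mapping[str, str] | None = None
) -> list[ActivityRecord]:
    """Parse an activity TSV/CSV into records.

    Rows with missing SMILES or an unparseable numeric value are dropped and
    counted in the log.  A missing mandatory column raises :class:`SchemaError`.
    """
    columns = {**DEFAULT_COLUMNS, **(dialect or {})}
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    mandatory = ["compound_id", "smiles", "target_id", "activity_type", "value"]
    for fieldname in mandatory:
        col = columns[fieldname]
        if col not in df.columns:
            raise SchemaError(f"activity table is missing mandatory column {col!r}")
    records: list[ActivityRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        smiles = row.get(columns["smiles"])
        raw_value = row.get(columns["value"])
        try:
            value = float(raw_value)
        except (TypeError, ValueError):
            value = float("nan")
        if not isinstance(smiles, str) or not smiles.strip() or not math.isfinite(value):
            dropped += 1
            continue
        records.append(
            ActivityRecord(
                compound_id=str(row[columns["compound_id"]]),
                smiles=smiles.strip(),
                target_id=str(row[columns["target_id"]]),
                target_name=str(row.get(columns["target_name"], "") or ""),
                target_type=str(row.get(columns["target_type"], "") or ""),
                organism=str(row.get(columns["organism"], "") or ""),
                activity_type=_normalize_activity_type(row[columns["activity_type"]]),
                value=value,
                unit=str(row.get(columns["unit"], "") or ""),
            )
        )
    if dropped:
        logger.info("load_activity_table: dropped %d malformed rows from %s", dropped, path)
    return records


def value_in_micromolar(record: ActivityRecord) -> float | None:
    """Record value converted to uM, or None when the unit is unconvertible."""
    factor = _UNIT_TO_UM.get(record.unit.strip())
    if factor is None:
        return None
    return record.value * factor


def filter_activities(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Keep records meeting the bioactivity cutoff.

    A record passes iff its activity type is a potency measure with value
    <= 10 uM (boundary inclusive, after unit conversion), or it is a percent
    inhibition strictly greater than 50%.  Unknown activity types and
    unconvertible units drop the record with a warning.
    """
    kept: list[ActivityRecord] = []
    for rec in records:
        if rec.activity_type in POTENCY_TYPES:
            um = value_in_micromolar(rec)
            if um is None:
                logger.warning(
                    "dropping %s/%s: unconvertible unit %r",
                    rec.compound_id, rec.target_id, rec.unit,
                )
                continue
            if um <= POTENCY_CUTOFF_UM:
                kept.append(rec)
        elif rec.activity_type == PERCENT_INHIBITION:
            if rec.value > INHIBITION_CUTOFF_PCT:
                kept.append(rec)
        else:
            logger.warning(
                "dropping %s/%s: unknown activity type %r",
                rec.compound_id, rec.target_id, rec.activity_type,
            )
    return kept


# ---------------------------------------------------------------------------
# group building
# ---------------------------------------------------------------------------


def build_target_groups(
    records: Sequence[ActivityRecord],
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
    source: str = "activity-table",
) -> ReferenceDatabase:
    """Standardize, deduplicate per target, retain groups of >= ``min_size``
    distinct actives and precompute fingerprint profiles.

    Deduplication keys on the canonical stereo-free SMILES; among duplicate
    structures the lexicographically smallest compound_id is kept, making
    membership independent of input order.
    """
    # standardize each unique input SMILES once
    std_cache: dict[str, Molecule | None] = {}

    def _std(smiles: str) -> Molecule | None:
        if smiles not in std_cache:
            try:
                std_cache[smiles] = standardize(smiles)
            except ChemError as exc:
                logger.warning("skipping unparseable structure: %s", exc)
                std_cache[smiles] = None
        return std_cache[smiles]

    per_target: dict[str, dict[str, str]] = {}  # target -> canonical smiles -> compound_id
    meta: dict[str, ActivityRecord] = {}
    for rec in records:
        mol = _std(rec.smiles)
        if mol is None:
            continue
        meta.setdefault(rec.target_id, rec)
        bucket = per_target.setdefault(rec.target_id, {})
        prev = bucket.get(mol.canonical_smiles)
        if prev is None or rec.compound_id < prev:
            bucket[mol.canonical_smiles] = rec.compound_id

    groups: list[TargetGroup] = []
    for target_id in sorted(per_target):
        bucket = per_target[target_id]
        if len(bucket) < min_size:
            continue
        rec = meta[target_id]
        members = tuple(
            sorted(((cid, smi) for smi, cid in bucket.items()), key=lambda m: m[0])
        )
        groups.append(
            TargetGroup(
                target_id=target_id,
                target_name=rec.target_name,
                target_type=rec.target_type,
                organism=rec.organism,
                members=members,
            )
        )
    if not groups:
        logger.warning("build_target_groups: no target retained at min_size=%d", min_size)

    profiles: dict[str, FingerprintProfile] = {}
    canonical: dict[str, str] = {}
    for g in groups:
        for cid, smi in g.members:
            if cid not in profiles:
                # profile from the canonical string, so spelling variants of
                # the same structure cannot leak into the fingerprints
                profiles[cid] = compute_profile(replace_id(smi, cid))
                canonical[cid] = smi
    return ReferenceDatabase(
        groups=groups,
        profiles=profiles,
        canonical_smiles=canonical,
        provenance={
            "source": source,
            "min_group_size": min_size,
            "built": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            "format_version": DB_FORMAT_VERSION,
        },
    )


def replace_id(canonical_smiles: str, compound_id: str) -> Molecule:
    """Standardized molecule from an already-canonical SMILES with a given id."""
    return standardize(canonical_smiles, mol_id=compound_id)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_database(db: ReferenceDatabase, directory: str) -> None:
    """Write the database as a directory: groups.json + profiles.tsv + checksums."""
    os.makedirs(directory, exist_ok=True)
    groups_path = os.path.join(directory, "groups.json")
    profiles_path = os.path.join(directory, "profiles.tsv")
    payload = {
        "format_version": DB_FORMAT_VERSION,
        "provenance": db.provenance,
        "canonical_smiles": db.canonical_smiles,
        "groups": [
            {
                "target_id": g.target_id,
                "target_name": g.target_name,
                "target_type": g.target_type,
                "organism": g.organism,
                "members": [list(m) for m in g.members],
            }
            for g in db.groups
        ],
    }
    with open(groups_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    ordered = sorted(db.profiles)
    profs = [db.profiles[cid] for cid in ordered]
    profiles_to_tsv(profs, profiles_path)
    checksums = {os.path.basename(p): _sha256(p) for p in (groups_path, profiles_path)}
    with open(os.path.join(directory, "checksums.json"), "w") as fh:
        json.dump(checksums, fh, indent=1)


def load_database(directory: str) -> ReferenceDatabase:
    """Inverse of :func:`save_database`; verifies checksums and format version."""
    groups_path = os.path.join(directory, "groups.json")
    profiles_path = os.path.join(directory, "profiles.tsv")
    checksum_path = os.path.join(directory, "checksums.json")
    if os.path.exists(checksum_path):
        with open(checksum_path) as fh:
            checksums = json.load(fh)
        for name, expected in checksums.items():
            actual = _sha256(os.path.join(directory, name))
            if actual != expected:
                raise DatabaseFormatError(f"checksum mismatch for {name} (corrupt database)")
    try:
        with open(groups_path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise DatabaseFormatError(f"cannot read {groups_path}: {exc}") from exc
    version = payload.get("format_version")
    if version != DB_FORMAT_VERSION:
        raise DatabaseFormatError(
            f"database format version {version} != supported {DB_FORMAT_VERSION}"
        )
    groups = [
        TargetGroup(
            target_id=g["target_id"],
            target_name=g["target_name"],
            target_type=g["target_type"],
            organism=g["organism"],
            members=tuple((cid, smi) for cid, smi in g["members"]),
        )
        for g in payload["groups"]
    ]
    profiles = {p.molecule_id: p for p in profiles_from_tsv(profiles_path)}
    missing = {cid for g in groups for cid in g.compound_ids} - set(profiles)
    if missing:
        raise DatabaseFormatError(f"profiles.tsv missing {len(missing)} member compounds")
    return ReferenceDatabase(
        groups=groups,
        profiles=profiles,
        canonical_smiles=payload.get("canonical_smiles", {}),
        provenance=payload.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# validation-set helper
# ---------------------------------------------------------------------------


def annotate_drugs(
    drugs: Sequence[tuple[str, str]],
    db: ReferenceDatabase,
    max_targets: int = 20,
) -> dict[str, tuple[str, list[str]]]:
    """Known-target annotation by exact canonical-SMILES match.

    ``drugs`` is a list of (drug_id, smiles).  Returns drug_id ->
    (canonical_smiles, sorted known target ids), keeping only drugs that
    match at least one group member and have at most ``max_targets`` targets.
    """
    smiles_to_targets: dict[str, set[str]] = {}
    for g in db.groups:
        for _, smi in g.members:
            smiles_to_targets.setdefault(smi, set()).add(g.target_id)
    out: dict[str, tuple[str, list[str]]] = {}
    for drug_id, smiles in drugs:
        try:
            mol = standardize(smiles, mol_id=drug_id)
        except ChemError:
            logger.warning("annotate_drugs: skipping unparseable drug %s", drug_id)
            continue
        targets = smiles_to_targets.get(mol.canonical_smiles)
        if targets and len(targets) <= max_targets:
            out[drug_id] = (mol.canonical_smiles, sorted(targets))
    return out
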