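"""Structure standardization and the six base molecular fingerprints.

The prediction engine compares molecules exclusively by city-block distance
between fixed-length fingerprint vectors.  Six complementary encodings are
used, spanning molecular shape (APfp), pharmacophore patterns (Xfp), global
composition (MQN), SMILES text composition (SMIfp) and detailed substructures
(Sfp, ECfp4):

================  ====  ======================================================
scheme            dim   encoding
================  ====  ======================================================
APfp                21  counts of heavy-atom pairs per topological distance
Xfp                 55  atom-category atom pairs (5 channels x 11 distance bins)
MQN                 42  molecular quantum numbers (atom/bond/polarity/ring counts)
SMIfp               34  character counts over the canonical SMILES string
Sfp               1024  Daylight-type hashed path fingerprint (binary)
ECfp4             1024  circular connectivity fingerprint, diameter 4 (binary)
================  ====  ======================================================

All fingerprints are computed on the heavy-atom graph with implicit hydrogens,
after stereochemistry removal and rule-based ionization at physiological pH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Lipinski, rdMolDescriptors, rdmolops
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

logger = logging.getLogger("ppb")

RDLogger.DisableLog("rdApp.warning")


class Scheme(str, Enum):
    """Fingerprint scheme identifiers: six base schemes plus four fused ones."""

    APfp = "APfp"
    Xfp = "Xfp"
    MQN = "MQN"
    SMIfp = "SMIfp"
    Sfp = "Sfp"
    ECfp4 = "ECfp4"
    Ffp1 = "Ffp1"
    Ffp2 = "Ffp2"
    Ffp3 = "Ffp3"
    Ffp4 = "Ffp4"

    def __str__(self) -> str:  # so f-strings print bare names
        return self.value


BASE_SCHEMES: tuple[Scheme, ...] = (
    Scheme.APfp,
    Scheme.Xfp,
    Scheme.MQN,
    Scheme.SMIfp,
    Scheme.Sfp,
    Scheme.ECfp4,
)

FUSED_SCHEMES: tuple[Scheme, ...] = (
    Scheme.Ffp1,
    Scheme.Ffp2,
    Scheme.Ffp3,
    Scheme.Ffp4,
)

ALL_SCHEMES: tuple[Scheme, ...] = BASE_SCHEMES + FUSED_SCHEMES

#: fixed dimensionality of each base scheme
SCHEME_DIMS: dict[Scheme, int] = {
    Scheme.APfp: 21,
    Scheme.Xfp: 55,
    Scheme.MQN: 42,
    Scheme.SMIfp: 34,
    Scheme.Sfp: 1024,
    Scheme.ECfp4: 1024,
}

BINARY_SCHEMES = frozenset({Scheme.Sfp, Scheme.ECfp4})

APFP_MAX_DIST = 21  # path lengths beyond this are clamped into the last bin
XFP_MAX_DIST = 11  # 11 distance bins per category channel (>=11 clamped)
XFP_CHANNELS = ("any-any", "HBA-HBA", "HBD-HBD", "HBA-HBD", "aromatic-aromatic")

#: 34-symbol SMIfp alphabet; two-character halogens are tokenized first.
SMIFP_ALPHABET: tuple[str, ...] = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "F", "Cl", "Br", "I", "B",
    "H", "(", ")", "[", "]", "=", "#", "+", "-", ".", "%",
    "1", "2", "3", "4", "5", "6", "7", "8", "9",
)

SFP_MAX_PATH = 7
SFP_BITS_PER_PATH = 2
ECFP_RADIUS = 2  # bond diameter 4

_morgan_gen = GetMorganGenerator(radius=ECFP_RADIUS, fpSize=SCHEME_DIMS[Scheme.ECfp4])


class ChemError(ValueError):
    """Raised for unparseable or chemically invalid input."""


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

# Rule-based ionization at pH 7.4: neutral acidic groups are deprotonated and
# neutral basic amines protonated.  Patterns deliberately match only the
# neutral form so that re-applying the rules is a no-op (idempotence).
_IONIZATION_RULES: tuple[tuple[str, str, int], ...] = (
    # (name, SMARTS for the atom to charge, charge delta)
    ("carboxylic-acid", "[CX3](=O)[OX2H1]", -1),
    ("sulfonic-acid", "[SX4](=O)(=O)[OX2H1]", -1),
    ("phosphonic-acid", "[PX4](=O)[OX2H1]", -1),
    ("tetrazole", "[nX3;H1]1nnnc1", -1),
    ("aliphatic-amine", "[NX3;H2,H1,H0;+0;!$(N=*);!$(N-[!#6;!#1]);!$(N-C=[O,N,S]);!$(N-a)]", +1),
    ("amidine-guanidine", "[NX2;H1,H0;+0]=[CX3]([NX3])", +1),
)
_COMPILED_RULES = tuple(
    (name, Chem.MolFromSmarts(smarts), delta) for name, smarts, delta in _IONIZATION_RULES
)


@dataclass(frozen=True)
class StandardizationOptions:
    """Options for :func:`standardize`.

    ionize: apply the rule-based pH 7.4 protonation rules (default on).
    """

    ionize: bool = True


@dataclass(frozen=True)
class Molecule:
    """A standardized input structure.

    ``canonical_smiles`` is stereo-free and toolkit-canonical; ``structure``
    holds the parsed RDKit molecule used for fingerprint computation.
    """

    source_smiles: str
    canonical_smiles: str
    structure: Chem.Mol = field(compare=False, repr=False)
    id: str = ""


def _apply_ionization(mol: Chem.Mol) -> tuple[Chem.Mol, list[str]]:
    """Set formal charges per the pH 7.4 rules; returns (mol, applied rule names)."""
    rw = Chem.RWMol(mol)
    applied: list[str] = []
    for name, pattern, delta in _COMPILED_RULES:
        if pattern is None:  # pragma: no cover - patterns are static
            continue
        matched_atoms: set[int] = set()
        for match in rw.GetMol().GetSubstructMatches(pattern):
            # the chargeable atom is the last atom of the SMARTS for acids
            # (the hydroxyl O / tetrazole N) and the first for bases
            idx = match[-1] if delta < 0 else match[0]
            matched_atoms.add(idx)
        for idx in matched_atoms:
            atom = rw.GetAtomWithIdx(idx)
            if atom.GetFormalCharge() != 0:
                continue
            if delta < 0:
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs()))
                atom.SetNoImplicit(False)
            else:
                atom.SetFormalCharge(+1)
            atom.UpdatePropertyCache(strict=False)
            applied.append(name)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out, applied


def standardize(
    smiles: str, options: StandardizationOptions | None = None, mol_id: str = ""
) -> Molecule:
    """Parse a SMILES, strip stereochemistry, apply pH 7.4 ionization rules
    and return the canonical stereo-free molecule.

    Deterministic and idempotent: standardizing ``canonical_smiles`` again
    yields the same string.

    Raises :class:`ChemError` on empty or unparseable input.
    """
    if options is None:
        options = StandardizationOptions()
    if not isinstance(smiles, str) or not smiles.strip():
        raise ChemError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    if options.ionize:
        mol, applied = _apply_ionization(mol)
        if applied:
            logger.debug("ionization rules applied to %r: %s", smiles, ", ".join(applied))
    canonical = Chem.MolToSmiles(mol)
    # reparse so the stored structure corresponds exactly to the canonical form
    structure = Chem.MolFromSmiles(canonical)
    if structure is None:  # pragma: no cover - canonical output always parses
        raise ChemError(f"canonicalization failed for {smiles!r}")
    return Molecule(
        source_smiles=smiles, canonical_smiles=canonical, structure=structure, id=mol_id
    )


# ---------------------------------------------------------------------------
# fingerprint vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FingerprintVector:
    """A fixed-length non-negative integer vector under one base scheme."""

    scheme: Scheme
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", vals)
        expected = SCHEME_DIMS[self.scheme]
        if vals.shape != (expected,):
            raise ValueError(
                f"{self.scheme} vector must have length {expected}, got {vals.shape}"
            )
        if (vals < 0).any():
            raise ValueError(f"{self.scheme} vector has negative entries")
        if self.scheme in BINARY_SCHEMES and not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{self.scheme} vector must be binary")

    def __len__(self) -> int:
        return self.values.shape[0]


def _require_heavy_atoms(mol: Molecule) -> Chem.Mol:
    struct = mol.structure
    if struct.GetNumHeavyAtoms() == 0:
        raise ChemError(f"molecule {mol.id or mol.canonical_smiles!r} has no heavy atoms")
    return struct


def compute_apfp(mol: Molecule) -> FingerprintVector:
    """21-D atom-pair fingerprint perceiving molecular shape.

    Bin ``d`` (1-based) counts unordered heavy-atom pairs at shortest
    topological path length ``d``; distances above 21 fall into bin 21.
    """
    struct = _require_heavy_atoms(mol)
    counts = np.zeros(APFP_MAX_DIST, dtype=np.int64)
    dm = rdmolops.GetDistanceMatrix(struct)
    n = struct.GetNumAtoms()
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dm[i, j])
            if d >= 1:
                counts[min(d, APFP_MAX_DIST) - 1] += 1
    return FingerprintVector(Scheme.APfp, counts)


def _atom_categories(struct: Chem.Mol) -> tuple[set[int], set[int], set[int]]:
    """Atom index sets (HBA, HBD, aromatic) under the toolkit's standard
    Lipinski donor/acceptor definitions."""
    hba = {m[0] for m in struct.GetSubstructMatches(Lipinski.HAcceptorSmarts)}
    hbd = {m[0] for m in struct.GetSubstructMatches(Lipinski.HDonorSmarts)}
    arom = {a.GetIdx() for a in struct.GetAtoms() if a.GetIsAromatic()}
    return hba, hbd, arom


def compute_xfp(mol: Molecule) -> FingerprintVector:
    """55-D category atom-pair fingerprint perceiving pharmacophore patterns.

    Five category channels — (any,any), (HBA,HBA), (HBD,HBD), (HBA,HBD) and
    (aromatic,aromatic) — each with 11 topological-distance bins (1..10,
    longer distances clamped into bin 11).
    """
    struct = _require_heavy_atoms(mol)
    counts = np.zeros(5 * XFP_MAX_DIST, dtype=np.int64)
    hba, hbd, arom = _atom_categories(struct)
    dm = rdmolops.GetDistanceMatrix(struct)
    n = struct.GetNumAtoms()
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dm[i, j])
            if d < 1:
                continue
            b = min(d, XFP_MAX_DIST) - 1
            counts[b] += 1  # channel 0: any-any
            if i in hba and j in hba:
                counts[XFP_MAX_DIST + b] += 1
            if i in hbd and j in hbd:
                counts[2 * XFP_MAX_DIST + b] += 1
            if (i in hba and j in hbd) or (i in hbd and j in hba):
                counts[3 * XFP_MAX_DIST + b] += 1
            if i in arom and j in arom:
                counts[4 * XFP_MAX_DIST + b] += 1
    return FingerprintVector(Scheme.Xfp, counts)


def compute_mqn(mol: Molecule) -> FingerprintVector:
    """42-D molecular quantum numbers (atom, bond, polarity and ring counts)."""
    struct = _require_heavy_atoms(mol)
    return FingerprintVector(Scheme.MQN, np.asarray(rdMolDescriptors.MQNs_(struct)))


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES into SMIfp symbols, consuming two-character halogens
    (Cl, Br) before single characters; symbols outside the alphabet are kept
    as tokens but ignored by the counter."""
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        two = smiles[i : i + 2]
        if two in ("Cl", "Br"):
            tokens.append(two)
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


def compute_smifp(mol: Molecule) -> FingerprintVector:
    """34-D SMILES character-count fingerprint over the canonical string."""
    counts = np.zeros(len(SMIFP_ALPHABET), dtype=np.int64)
    index = {sym: k for k, sym in enumerate(SMIFP_ALPHABET)}
    for tok in tokenize_smiles(mol.canonical_smiles):
        k = index.get(tok)
        if k is not None:
            counts[k] += 1
    return FingerprintVector(Scheme.SMIfp, counts)


def compute_sfp(mol: Molecule) -> FingerprintVector:
    """1024-bit Daylight-type hashed path fingerprint (paths up to length 7)."""
    struct = _require_heavy_atoms(mol)
    bv = Chem.RDKFingerprint(
        struct,
        maxPath=SFP_MAX_PATH,
        fpSize=SCHEME_DIMS[Scheme.Sfp],
        nBitsPerHash=SFP_BITS_PER_PATH,
    )
    arr = np.zeros(SCHEME_DIMS[Scheme.Sfp], dtype=np.int64)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return FingerprintVector(Scheme.Sfp, arr)


def compute_ecfp4(mol: Molecule) -> FingerprintVector:
    """1024-bit circular extended-connectivity fingerprint, bond diameter 4."""
    struct = _require_heavy_atoms(mol)
    bv = _morgan_gen.GetFingerprint(struct)
    arr = np.zeros(SCHEME_DIMS[Scheme.ECfp4], dtype=np.int64)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return FingerprintVector(Scheme.ECfp4, arr)


_COMPUTE = {
    Scheme.APfp: compute_apfp,
    Scheme.Xfp: compute_xfp,
    Scheme.MQN: compute_mqn,
    Scheme.SMIfp: compute_smifp,
    Scheme.Sfp: compute_sfp,
    Scheme.ECfp4: compute_ecfp4,
}


@dataclass(frozen=True)
class FingerprintProfile:
    """The six base fingerprint vectors of one molecule.

    Fused fingerprints are never stored; they are derived on demand from the
    base vectors and a scaling table (see :mod:`ppb.distance_fusion`).
    """

    molecule_id: str
    vectors: dict[Scheme, FingerprintVector]

    def __post_init__(self) -> None:
        missing = [s for s in BASE_SCHEMES if s not in self.vectors]
        if missing:
            raise ValueError(f"profile missing schemes: {missing}")

    def __getitem__(self, scheme: Scheme) -> FingerprintVector:
        return self.vectors[scheme]


def compute_profile(mol: Molecule) -> FingerprintProfile:
    """Compute all six base fingerprints for a standardized molecule."""
    vectors = {scheme: fn(mol) for scheme, fn in _COMPUTE.items()}
    return FingerprintProfile(molecule_id=mol.id or mol.canonical_smiles, vectors=vectors)


def compute_profiles(mols: Iterable[Molecule]) -> list[FingerprintProfile]:
    """Profiles for a batch of molecules, input order preserved."""
    return [compute_profile(m) for m in mols]


# ---------------------------------------------------------------------------
# simple I/O
# ---------------------------------------------------------------------------


def read_smiles_file(path: str) -> list[Molecule]:
    """Read a SMILES file (one molecule per line, optional tab-separated id)."""
    out: list[Molecule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
            out.append(standardize(smi, mol_id=mol_id))
    return out


def read_sdf_file(path: str) -> list[Molecule]:
    """Read molecules from an SDF file, standardizing each record."""
    out: list[Molecule] = []
    for i, raw in enumerate(Chem.SDMolSupplier(path)):
        if raw is None:
            logger.warning("skipping unparseable SDF record %d in %s", i, path)
            continue
        name = raw.GetProp("_Name") if raw.HasProp("_Name") else f"mol{i + 1}"
        out.append(standardize(Chem.MolToSmiles(raw), mol_id=name))
    return out


def profiles_to_tsv(profiles: Sequence[FingerprintProfile], path: str) -> None:
    """Write profiles as a columnar TSV with scheme/dimension headers."""
    header = ["molecule_id"]
    for scheme in BASE_SCHEMES:
        header.extend(f"{scheme}_{k}" for k in range(SCHEME_DIMS[scheme]))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in profiles:
            row = [p.molecule_id]
            for scheme in BASE_SCHEMES:
                row.extend(str(int(v)) for v in p[scheme].values)
            fh.write("\t".join(row) + "\n")


def profiles_from_tsv(path: str) -> list[FingerprintProfile]:
    """Inverse of :func:`profiles_to_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = 1 + sum(SCHEME_DIMS[s] for s in BASE_SCHEMES)
        if len(header) != expected:
            raise ValueError(f"profile table has {len(header)} columns, expected {expected}")
        out: list[FingerprintProfile] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            mol_id, vals = parts[0], [int(v) for v in parts[1:]]
            vectors: dict[Scheme, FingerprintVector] = {}
            off = 0
            for scheme in BASE_SCHEMES:
                k = SCHEME_DIMS[scheme]
                vectors[scheme] = FingerprintVector(scheme, np.array(vals[off : off + k]))
                off += k
            out.append(FingerprintProfile(molecule_id=mol_id, vectors=vectors))
    return out
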