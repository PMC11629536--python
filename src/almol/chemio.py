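"""Molecule parsing, fingerprints, scaffolds, similarity and fixture libraries.

Molecules are represented by their canonical SMILES together with a
fixed-length Morgan *count* fingerprint (ECFP-style circular environments)
and a Murcko scaffold key.  Count vectors feed the property predictor;
similarity computations binarize them to presence bits first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import CapacityError, DimensionError, MoleculeParseError

RDLogger.DisableLog("rdApp.*")


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular-fingerprint settings: radius 3, length 2048 by default."""

    radius: int = 3
    length: int = 2048
    counted: bool = True

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")


@dataclass(frozen=True)
class Molecule:
    """A canonical SMILES plus its count fingerprint and scaffold key.

    ``scaffold_key`` is the SMILES of the Murcko ring framework, or the
    empty string for acyclic molecules.
    """

    smiles: str
    fingerprint: np.ndarray = field(compare=False, repr=False)
    scaffold_key: str = field(compare=False)

    def __hash__(self) -> int:  # identity is the canonical SMILES
        return hash(self.smiles)


_GENERATOR_CACHE: dict[tuple[int, int], object] = {}


def _fp_generator(cfg: FingerprintConfig):
    key = (cfg.radius, cfg.length)
    if key not in _GENERATOR_CACHE:
        _GENERATOR_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=cfg.radius, fpSize=cfg.length
        )
    return _GENERATOR_CACHE[key]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    # the toolkit parses "" as a zero-atom molecule; reject it up front
    mol = Chem.MolFromSmiles(smiles) if smiles.strip() else None
    if mol is None:
        raise MoleculeParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the toolkit-canonical SMILES; idempotent by construction."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def ecfp_count(smiles: str, cfg: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Hashed circular-environment count vector of length ``cfg.length``."""
    mol = _mol_from_smiles(smiles)
    fp = _fp_generator(cfg).GetCountFingerprint(mol)
    vec = np.zeros(cfg.length, dtype=np.int64)
    for idx, count in fp.GetNonzeroElements().items():
        vec[idx] = count
    return vec


def scaffold_key(smiles: str) -> str:
    """Murcko ring-framework SMILES; empty string for acyclic molecules."""
    mol = _mol_from_smiles(smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def molecule_from_smiles(
    smiles: str, cfg: FingerprintConfig = FingerprintConfig()
) -> Molecule:
    """Parse, canonicalize and featurize a SMILES string into a Molecule."""
    canonical = canonicalize(smiles)
    return Molecule(
        smiles=canonical,
        fingerprint=ecfp_count(canonical, cfg),
        scaffold_key=scaffold_key(canonical),
    )


def fingerprint_matrix(molecules: Sequence[Molecule]) -> np.ndarray:
    """Stack molecule count fingerprints into an ``(n, D)`` matrix."""
    return np.vstack([m.fingerprint for m in molecules])


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity on presence bits: ``|a & b| / |a | b|``.

    Count vectors are binarized to their nonzero support first.  Two empty
    vectors compare as 0.
    """
    a = np.asarray(fp_a)
    b = np.asarray(fp_b)
    if a.shape != b.shape:
        raise DimensionError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    a = a > 0
    b = b > 0
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Pairwise presence-bit Tanimoto between two fingerprint matrices."""
    a = (np.atleast_2d(fps_a) > 0).astype(np.float64)
    b = (np.atleast_2d(fps_b) > 0).astype(np.float64)
    if a.shape[1] != b.shape[1]:
        raise DimensionError("fingerprint lengths differ")
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


# --- fixture library ---------------------------------------------------------
#
# A deterministic combinatorial library: ring scaffolds decorated with small
# substituents at one or two positions.  It stands in for a generated or
# database pool so that every stage of the loop is testable offline, with
# guaranteed-valid SMILES spanning many Murcko scaffolds.

_SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    # one substitution site
    "c1ccc({0})cc1",          # benzene
    "c1ccnc({0})c1",          # pyridine
    "c1cnc({0})nc1",          # pyrimidine
    "c1ccc2[nH]c({0})cc2c1",  # indole
    "c1ccc2c(c1)cccc2{0}",    # naphthalene
    "C1CCN({0})CC1",          # piperidine
    "C1COCCN1{0}",            # morpholine
    "c1cc({0})cs1",           # thiophene
    "c1cc({0})co1",           # furan
    "c1cc({0})n[nH]1",        # pyrazole
    "c1cnc2ccccc2c1{0}",      # isoquinoline
    "C1CCC({0})CC1",          # cyclohexane
    "C1CN({0})CCN1C",         # N-methylpiperazine
    "c1nc({0})cs1",           # thiazole
    "c1cc2ccccc2o1",          # benzofuran (undecorated)
    # two substitution sites
    "c1cc({0})ccc1{1}",       # para-disubstituted benzene
    "c1cc({0})cnc1{1}",       # disubstituted pyridine
    "C1CC({0})CCN1{1}",       # disubstituted piperidine
    "c1c({0})sc({1})c1",      # disubstituted thiophene
    "O=C(c1ccccc1{0})N{1}",   # benzamide
    "c1nc({0})nc({1})c1",     # 2,4-disubstituted pyrimidine
    "C1CN({0})CCN1{1}",       # 1,4-disubstituted piperazine
    "C1CC({0})CCC1{1}",       # 1,4-disubstituted cyclohexane
    "c1c({0})cc(n1C)C(=O)N{1}",  # N-methylpyrrole carboxamide
    "O=C(O{0})c1ccc({1})cc1",    # substituted benzoate ester
)

_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N",
    "C(F)(F)F", "S(C)(=O)=O", "CO", "CCO", "CN", "C=C", "CC#N",
    "OC(C)C", "CCl", "CCN", "C(C)=O", "OC(F)F",
)


def _enumerate_library() -> Iterable[str]:
    for template in _SCAFFOLD_TEMPLATES:
        n_sites = template.count("{")
        if n_sites == 0:
            yield template
        elif n_sites == 1:
            for sub in _SUBSTITUENTS:
                yield template.format(sub)
        else:
            for s0, s1 in itertools.product(_SUBSTITUENTS, repeat=2):
                yield template.format(s0, s1)


_LIBRARY_SMILES: list[str] | None = None
_LIBRARY_CACHE: dict[tuple[int, int, FingerprintConfig], list[Molecule]] = {}


def _library_smiles() -> list[str]:
    global _LIBRARY_SMILES
    if _LIBRARY_SMILES is None:
        seen: dict[str, None] = {}
        for raw in _enumerate_library():
            seen.setdefault(canonicalize(raw), None)
        _LIBRARY_SMILES = list(seen)
    return _LIBRARY_SMILES


def fixture_library(
    seed: int, n: int, cfg: FingerprintConfig = FingerprintConfig()
) -> list[Molecule]:
    """Build ``n`` unique molecules by scaffold x substituent enumeration.

    The full enumeration is canonicalized and deduplicated in a fixed order,
    then shuffled with a seeded generator, so the result is deterministic per
    seed.  Requests beyond the enumerable size raise :class:`CapacityError`.
    Results are memoized per ``(seed, n, cfg)`` within a process.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    key = (seed, n, cfg)
    if key in _LIBRARY_CACHE:
        return list(_LIBRARY_CACHE[key])
    unique = _library_smiles()
    if n > len(unique):
        raise CapacityError(
            f"requested {n} molecules but the library enumerates only {len(unique)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))[:n]
    molecules = [molecule_from_smiles(unique[i], cfg) for i in order]
    _LIBRARY_CACHE[key] = molecules
    return list(molecules)


# --- file I/O ----------------------------------------------------------------

def read_smi(path: str | Path) -> list[str]:
    """Read a SMILES file: one record per line, optional tab-separated name.

    Blank lines and lines starting with ``#`` are ignored.
    """
    smiles = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles.append(line.split("\t")[0].split()[0])
    return smiles


def write_smi(path: str | Path, smiles: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in smiles), encoding="utf-8")


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV with a ``smiles`` column (and optionally ``label``)."""
    from .errors import ConfigurationError

    df = pd.read_csv(path, comment="#")
    if "smiles" not in df.columns:
        raise ConfigurationError(
            f"{path}: expected a 'smiles' column, found {list(df.columns)}"
        )
    return df


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
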