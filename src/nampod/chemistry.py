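"""Chemical identity, molecular descriptors, Lipinski screening and fingerprints.

Descriptors are computed with RDKit on the neutral parent structure
(largest organic fragment after salt/counter-ion stripping).  Binary
fingerprints are held as a wide 0/1 matrix (one row per chemical, one
column per named bit) so that externally computed dictionaries such as
ToxPrint or PubChem fingerprints and internally computed Morgan
fingerprints share one representation and one Tanimoto code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: HBD/HBA convention: RDKit's Lipinski definitions (NumHDonors counts O-H and
#: N-H; NumHAcceptors counts N and O atoms).  Recorded in output metadata.
HBOND_CONVENTION = "rdkit-lipinski"

RULE_OF_FIVE_THRESHOLDS = {"MW>500": 500.0, "logP>5": 5.0, "HBD>5": 5, "HBA>10": 10}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, chem_id: str | None = None):
        self.smiles = smiles
        self.chem_id = chem_id
        ident = f" for chemical {chem_id!r}" if chem_id else ""
        super().__init__(f"unparseable SMILES {smiles!r}{ident}")


class MissingDescriptorError(ValueError):
    """Raised when a rule-of-five check is asked for with a descriptor absent."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing descriptor field {field!r}")


@dataclass
class ChemicalRecord:
    """One chemical with identity, structure and the fields the filters consume.

    ``fraction_absorbed`` / ``fraction_bioavailable`` and
    ``in_applicability_domain`` belong to predicted toxicokinetic parameters
    and are only required when the chemical flows through the eligibility
    filter with predicted parameters.
    """

    chem_id: str
    smiles: str | None = None
    mw: float | None = None
    logp: float | None = None
    hbd: int | None = None
    hba: int | None = None
    fraction_absorbed: float | None = None
    fraction_bioavailable: float | None = None
    in_applicability_domain: bool = True
    cramer_class: str | None = None


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Strip salts/counter-ions by keeping the fragment with most heavy atoms."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def parse_smiles(smiles: str, chem_id: str | None = None) -> Chem.Mol:
    if not smiles or not isinstance(smiles, str):
        raise SmilesParseError(str(smiles), chem_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, chem_id)
    return _largest_fragment(mol)


def compute_descriptors(smiles: str, chem_id: str | None = None) -> tuple[float, float, int, int]:
    """Return (mw, logp, hbd, hba) for the neutral parent structure.

    mw is the average molecular weight in Da, logp the Crippen estimate of
    the octanol/water partition coefficient, hbd/hba the Lipinski hydrogen
    bond donor/acceptor counts (see :data:`HBOND_CONVENTION`).
    """
    mol = parse_smiles(smiles, chem_id)
    return (
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
    )


def rule_of_five_violations(record) -> list[str]:
    """Return the violated Lipinski criteria for a chemical.

    Accepts a :class:`ChemicalRecord`, mapping or pandas row with fields
    ``mw, logp, hbd, hba``.  Thresholds are strict: a value exactly at the
    bound (MW = 500, logP = 5, HBD = 5, HBA = 10) is not a violation.
    """
    get = record.get if isinstance(record, Mapping) else lambda f, d=None: getattr(record, f, d)
    values = {}
    for f in ("mw", "logp", "hbd", "hba"):
        v = get(f)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingDescriptorError(f)
        values[f] = v
    violations = []
    if values["hbd"] > 5:
        violations.append("HBD>5")
    if values["hba"] > 10:
        violations.append("HBA>10")
    if values["mw"] > 500:
        violations.append("MW>500")
    if values["logp"] > 5:
        violations.append("logP>5")
    return violations


# ---------------------------------------------------------------------------
# fingerprints


@dataclass
class Fingerprint:
    """One chemical's binary fingerprint over a named bit dictionary."""

    chem_id: str
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits).astype(np.uint8)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between two bit vectors.

    Accepts :class:`Fingerprint` objects or 0/1 arrays over the same bit
    dictionary.  Two all-zero vectors have an undefined ratio; 0.0 is
    returned with a warning (such chemicals never pass the >5-on-bits
    eligibility rule, so the value never drives a prediction).
    """
    va = a.bits if isinstance(a, Fingerprint) else np.asarray(a)
    vb = b.bits if isinstance(b, Fingerprint) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError("fingerprints use different bit dictionaries (lengths differ)")
    va = va.astype(bool)
    vb = vb.astype(bool)
    union = int(np.logical_or(va, vb).sum())
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0", stacklevel=2)
        return 0.0
    return int(np.logical_and(va, vb).sum()) / union


def tanimoto_matrix(fps: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Tanimoto similarity for a fingerprint matrix.

    ``fps``: chemicals x bits 0/1 DataFrame indexed by chem_id.  All-zero
    rows get similarity 0 to everything (including themselves).
    """
    x = fps.to_numpy(dtype=np.int64)
    inter = x @ x.T
    n_on = x.sum(axis=1)
    union = n_on[:, None] + n_on[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return pd.DataFrame(sim, index=fps.index, columns=fps.index)


def tanimoto_cross(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Tanimoto similarities between two fingerprint matrices (rows of a x rows of b)."""
    if list(a.columns) != list(b.columns):
        raise ValueError("fingerprint matrices use different bit dictionaries")
    xa = a.to_numpy(dtype=np.int64)
    xb = b.to_numpy(dtype=np.int64)
    inter = xa @ xb.T
    union = xa.sum(axis=1)[:, None] + xb.sum(axis=1)[None, :] - inter
    sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return pd.DataFrame(sim, index=a.index, columns=b.index)


def morgan_fingerprints(
    smiles_by_id: Mapping[str, str], radius: int = 2, n_bits: int = 1024
) -> tuple[pd.DataFrame, list[str]]:
    """Compute Morgan (ECFP-like) fingerprints for a set of chemicals.

    Returns a (chemicals x bits) 0/1 DataFrame plus the list of chem_ids
    skipped because their SMILES could not be parsed.  Deterministic for a
    given structure, radius and width.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, index, skipped = [], [], []
    for chem_id, smiles in smiles_by_id.items():
        try:
            mol = parse_smiles(smiles, chem_id)
        except SmilesParseError:
            skipped.append(chem_id)
            continue
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        rows.append(arr)
        index.append(chem_id)
    cols = [f"morgan_{i}" for i in range(n_bits)]
    if not rows:
        return pd.DataFrame(columns=cols, dtype=np.uint8), skipped
    return pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="chem_id"), columns=cols), skipped


def read_fingerprints(path) -> pd.DataFrame:
    """Read a wide fingerprint CSV/TSV (chem_id + one 0/1 column per bit)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col="chem_id")
    return df.astype(np.uint8)


def write_fingerprints(fps: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    fps.to_csv(path, sep=sep, index_label="chem_id")
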