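"""Chemical structural similarity between compounds from SMILES.

Two families of coefficients are computed for each drug pair:

* fingerprint Tanimoto — bit-set intersection over union for a configurable
  binary fingerprint (default: RDKit path-based, 2048 bits);
* MCS coefficients — from the maximum common substructure of the pair,
  counted in heavy atoms m: the MCS Tanimoto m / (n_a + n_b - m) and the
  structural overlap m / min(n_a, n_b), which quantifies substructure
  inclusion. These are the conventions of MCS toolkits such as fmcsR.

A partition-concordance helper (adjusted Rand index plus contingency
table) scores agreement between structural clusters and clusters derived
from pharmacogenomic target-set similarity.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs, rdFMCS
from sklearn.metrics import adjusted_rand_score

from . import cluster as _cluster

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "StructSimRecord",
    "cluster_concordance",
    "fingerprint_tanimoto",
    "load_compounds",
    "mcs_coefficients",
    "pairwise_structural",
    "select_matrix_by_cophenetic",
]

FP_KINDS = ("path2048", "morgan2048", "maccs")


@dataclass(frozen=True)
class CompoundRecord:
    drug_id: str
    smiles: str

    @property
    def mol(self):
        m = Chem.MolFromSmiles(self.smiles)
        if m is None or m.GetNumHeavyAtoms() < 1:
            raise ValueError(f"unparseable SMILES for {self.drug_id}: {self.smiles!r}")
        return m


@dataclass(frozen=True)
class StructSimRecord:
    drug_a: str
    drug_b: str
    fp_tanimoto: float
    mcs_atoms: int
    mcs_tanimoto: float
    mcs_overlap: float
    timed_out: bool = False


def load_compounds(path) -> tuple[list[CompoundRecord], list[str]]:
    """Parse a .smi file (``SMILES<ws>id`` per line) or a TSV (drug_id, smiles).

    Unparseable lines are collected in the returned error report rather
    than raising; zero valid records raises.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    errors: list[str] = []

    def try_add(drug_id: str, smiles: str, lineno: int) -> None:
        if Chem.MolFromSmiles(smiles) is None:
            errors.append(f"line {lineno}: unparseable SMILES {smiles!r} ({drug_id})")
        else:
            records.append(CompoundRecord(drug_id=drug_id, smiles=smiles))

    text = path.read_text().splitlines()
    header_cols = text[0].rstrip("\n").split("\t") if text else []
    if "smiles" in header_cols:  # TSV with a header row
        id_col = header_cols.index("drug_id") if "drug_id" in header_cols else 0
        smi_col = header_cols.index("smiles")
        for i, line in enumerate(text[1:], start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(id_col, smi_col) or not line.strip():
                errors.append(f"line {i}: malformed row {line!r}")
                continue
            try_add(parts[id_col], parts[smi_col], i)
    else:  # .smi dialect: SMILES, whitespace, id; '#' comments allowed
        for i, line in enumerate(text, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                errors.append(f"line {i}: expected 'SMILES id', got {line!r}")
                continue
            try_add(parts[1], parts[0], i)
    if not records:
        raise ValueError(f"no valid compound records in {path}")
    return records, errors


def _fingerprint(mol, fp_kind: str):
    if fp_kind == "path2048":
        return Chem.RDKFingerprint(mol, fpSize=2048)
    if fp_kind == "morgan2048":
        return AllChem.GetMorganFingerprintAsBitVect(mol, radius=2, nBits=2048)
    if fp_kind == "maccs":
        from rdkit.Chem import MACCSkeys
        return MACCSkeys.GenMACCSKeys(mol)
    raise ValueError(f"unknown fingerprint kind {fp_kind!r}; expected one of {FP_KINDS}")


def fingerprint_tanimoto(a: CompoundRecord, b: CompoundRecord,
                         fp_kind: str = "path2048") -> float:
    """Tanimoto coefficient of the two compounds' binary fingerprints."""
    return float(DataStructs.TanimotoSimilarity(
        _fingerprint(a.mol, fp_kind), _fingerprint(b.mol, fp_kind)
    ))


def mcs_coefficients(a: CompoundRecord, b: CompoundRecord,
                     atom_mismatch: int = 0, bond_mismatch: int = 0,
                     timeout: int = 30, fp_kind: str = "path2048") -> StructSimRecord:
    """MCS-based Tanimoto and overlap coefficients for one compound pair.

    ``atom_mismatch`` / ``bond_mismatch`` > 0 relax the element / bond-order
    matching (any-atom / any-bond comparison), mirroring MCS engines that
    tolerate minor mismatches. A timed-out search flags the record and
    leaves the coefficients missing.
    """
    ma, mb = a.mol, b.mol
    params = rdFMCS.MCSParameters()
    params.Timeout = timeout
    params.AtomTyper = (rdFMCS.AtomCompare.CompareAny if atom_mismatch > 0
                        else rdFMCS.AtomCompare.CompareElements)
    params.BondTyper = (rdFMCS.BondCompare.CompareAny if bond_mismatch > 0
                        else rdFMCS.BondCompare.CompareOrder)
    result = rdFMCS.FindMCS([ma, mb], params)
    na, nb = ma.GetNumHeavyAtoms(), mb.GetNumHeavyAtoms()
    if result.canceled:
        return StructSimRecord(a.drug_id, b.drug_id,
                               fingerprint_tanimoto(a, b, fp_kind),
                               0, float("nan"), float("nan"), timed_out=True)
    m = result.numAtoms
    return StructSimRecord(
        drug_a=a.drug_id, drug_b=b.drug_id,
        fp_tanimoto=fingerprint_tanimoto(a, b, fp_kind),
        mcs_atoms=m,
        mcs_tanimoto=m / (na + nb - m) if na + nb - m > 0 else 1.0,
        mcs_overlap=m / min(na, nb),
    )


def pairwise_structural(
    records: Iterable[CompoundRecord],
    fp_kind: str = "path2048",
    atom_mismatch: int = 0,
    bond_mismatch: int = 0,
    timeout: int = 30,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """All-against-all structural comparison.

    Returns symmetric per-coefficient matrices (``fp_tanimoto``,
    ``mcs_tanimoto``, ``mcs_overlap``; unit diagonal) and the full square
    pair table with one row per ordered cell, diagonal included — n
    compounds give n^2 rows.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 compounds")
    ids = [r.drug_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate drug ids among compounds")
    n = len(records)
    mats = {k: np.eye(n) for k in ("fp_tanimoto", "mcs_tanimoto", "mcs_overlap")}
    for i, j in itertools.combinations(range(n), 2):
        rec = mcs_coefficients(records[i], records[j], atom_mismatch,
                               bond_mismatch, timeout, fp_kind)
        for key in mats:
            mats[key][i, j] = mats[key][j, i] = getattr(rec, key)
    matrices = {
        k: pd.DataFrame(v, index=ids, columns=ids) for k, v in mats.items()
    }
    for k, df in matrices.items():
        df.attrs["index_name"] = k

    rows = []
    for i in range(n):
        for j in range(n):
            rows.append((
                ids[i], ids[j],
                mats["fp_tanimoto"][i, j],
                mats["mcs_tanimoto"][i, j],
                mats["mcs_overlap"][i, j],
            ))
    table = pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "fp_tanimoto", "mcs_tanimoto", "mcs_overlap"]
    )
    return matrices, table


def select_matrix_by_cophenetic(
    matrices: Mapping[str, pd.DataFrame]
) -> tuple[str, "_cluster.ClusterTree", float]:
    """Pick the structural matrix whose average-linkage tree best preserves it.

    Each candidate similarity matrix is converted to distances and
    clustered with average linkage; the matrix with the highest cophenetic
    correlation wins. Returns (name, tree, cophenetic correlation).
    """
    best = None
    for name in sorted(matrices):
        dist = _cluster.to_distance(matrices[name])
        tree = _cluster.ward_cluster(dist, linkage_name="average")
        c = _cluster.cophenetic_correlation(tree, dist)
        if best is None or c > best[2]:
            best = (name, tree, c)
    assert best is not None
    return best


def cluster_concordance(p1: pd.Series, p2: pd.Series) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index and contingency table of two partitions."""
    if set(p1.index) != set(p2.index):
        raise ValueError("partitions must cover the same ids")
    p2 = p2.loc[p1.index]
    ari = float(adjusted_rand_score(p1.to_numpy(), p2.to_numpy()))
    table = pd.crosstab(p1, p2)
    return ari, table
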