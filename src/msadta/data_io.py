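"""Readers/writers for affinity datasets and fold splitting.

The canonical on-disk layout is plain text, diffable and portable:

* ``drugs.csv`` — columns ``id,smiles`` (isomeric SMILES kept verbatim);
* ``proteins.csv`` — columns ``id,sequence``;
* ``affinities.csv`` — columns ``drug_id,protein_id,value`` (missing pairs
  simply absent, so sparse benchmarks like KIBA need no sentinel);
* ``folds.json`` — optional fold labels aligned with the affinity rows.

The DeepDTA benchmark release (JSON ligand/protein dictionaries plus a
pickled affinity matrix, NaN for unmeasured pairs) is read if present but
never written.
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import kd_to_pkd

TEST_LABEL = "test"

__all__ = ["AffinityDataset", "load_dataset", "save_dataset", "split_folds", "TEST_LABEL"]


@dataclass(frozen=True)
class AffinityDataset:
    """Drug table + protein table + (drug, protein, affinity) triples.

    ``folds`` (optional) assigns each triple either an integer cross-
    validation fold ``0..k-1`` or the string ``"test"``.
    """

    drugs: dict[str, str]
    proteins: dict[str, str]
    triples: tuple[tuple[str, str, float], ...]
    folds: tuple[int | str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "triples", tuple(tuple(t) for t in self.triples))
        if self.folds is not None:
            object.__setattr__(self, "folds", tuple(self.folds))
            if len(self.folds) != len(self.triples):
                raise ValueError("folds must align with triples")
        for d, p, v in self.triples:
            if d not in self.drugs:
                raise ValueError(f"triple references unknown drug id {d!r}")
            if p not in self.proteins:
                raise ValueError(f"triple references unknown protein id {p!r}")
            if not math.isfinite(v):
                raise ValueError(f"non-finite affinity for ({d}, {p})")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def is_dense(self) -> bool:
        return len(self.triples) == self.n_drugs * self.n_proteins

    def affinities(self) -> np.ndarray:
        return np.array([v for _, _, v in self.triples], dtype=float)

    def indices_for(self, label: int | str) -> np.ndarray:
        if self.folds is None:
            raise ValueError("dataset has no fold assignment")
        return np.array([i for i, f in enumerate(self.folds) if f == label], dtype=int)

    def train_indices(self, exclude_fold: int | None = None) -> np.ndarray:
        """All non-test triples, optionally holding one CV fold out."""
        if self.folds is None:
            raise ValueError("dataset has no fold assignment")
        return np.array(
            [
                i
                for i, f in enumerate(self.folds)
                if f != TEST_LABEL and f != exclude_fold
            ],
            dtype=int,
        )


def load_dataset(
    path: str | Path, format: str = "csv", kd_transform: bool = False
) -> AffinityDataset:
    """Load an affinity dataset directory.

    ``format="csv"`` reads the canonical layout above; ``format="deepdta"``
    reads a DeepDTA-style release (``ligands_can.txt`` / ``proteins.txt``
    JSON dicts and an affinity matrix ``Y`` stored as .npy or pickle).
    ``kd_transform=True`` converts raw Kd values in nM to pKd on load, the
    convention for the Davis kinase benchmark.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {path}")
    if format == "csv":
        ds = _load_csv(path)
    elif format == "deepdta":
        ds = _load_deepdta(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if kd_transform:
        ds = replace(
            ds,
            triples=tuple((d, p, float(kd_to_pkd(v))) for d, p, v in ds.triples),
        )
    return ds


def _read_table(path: Path, cols: tuple[str, str]) -> dict[str, str]:
    if not path.exists():
        raise FileNotFoundError(f"missing dataset file: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    if df[cols[0]].duplicated().any():
        raise ValueError(f"{path.name}: duplicate ids")
    return dict(zip(df[cols[0]], df[cols[1]]))


def _load_csv(path: Path) -> AffinityDataset:
    drugs = _read_table(path / "drugs.csv", ("id", "smiles"))
    proteins = _read_table(path / "proteins.csv", ("id", "sequence"))
    aff_path = path / "affinities.csv"
    if not aff_path.exists():
        raise FileNotFoundError(f"missing dataset file: {aff_path}")
    aff = pd.read_csv(aff_path, dtype={"drug_id": str, "protein_id": str})
    for col in ("drug_id", "protein_id", "value"):
        if col not in aff.columns:
            raise ValueError(f"affinities.csv: missing column {col!r}")
    values = pd.to_numeric(aff["value"], errors="coerce")
    if values.isna().any():
        bad = aff.loc[values.isna()].iloc[0]
        raise ValueError(
            f"affinities.csv: non-numeric affinity for "
            f"({bad['drug_id']}, {bad['protein_id']})"
        )
    triples = tuple(
        (d, p, float(v)) for d, p, v in zip(aff["drug_id"], aff["protein_id"], values)
    )
    folds = None
    folds_path = path / "folds.json"
    if folds_path.exists():
        labels = json.loads(folds_path.read_text())["labels"]
        folds = tuple(label if label == TEST_LABEL else int(label) for label in labels)
    return AffinityDataset(drugs=drugs, proteins=proteins, triples=triples, folds=folds)


def _load_deepdta(path: Path) -> AffinityDataset:
    lig_path = path / "ligands_can.txt"
    prot_path = path / "proteins.txt"
    for p in (lig_path, prot_path):
        if not p.exists():
            raise FileNotFoundError(f"missing dataset file: {p}")
    drugs = {str(k): str(v) for k, v in json.loads(lig_path.read_text()).items()}
    proteins = {str(k): str(v) for k, v in json.loads(prot_path.read_text()).items()}
    y_path = next((path / name for name in ("Y", "Y.npy") if (path / name).exists()), None)
    if y_path is None:
        raise FileNotFoundError(f"missing affinity matrix Y in {path}")
    try:
        Y = np.load(y_path, allow_pickle=True)
    except (ValueError, OSError):
        with open(y_path, "rb") as fh:
            Y = pickle.load(fh, encoding="latin1")
    Y = np.asarray(Y, dtype=float)
    drug_ids = list(drugs)
    prot_ids = list(proteins)
    if Y.shape != (len(drug_ids), len(prot_ids)):
        raise ValueError(
            f"affinity matrix shape {Y.shape} does not match "
            f"{len(drug_ids)} drugs x {len(prot_ids)} proteins"
        )
    triples = tuple(
        (drug_ids[i], prot_ids[j], float(Y[i, j]))
        for i in range(Y.shape[0])
        for j in range(Y.shape[1])
        if math.isfinite(Y[i, j])
    )
    return AffinityDataset(drugs=drugs, proteins=proteins, triples=triples)


def save_dataset(dataset: AffinityDataset, path: str | Path) -> None:
    """Write the canonical CSV/JSON layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"id": list(dataset.drugs), "smiles": list(dataset.drugs.values())}
    ).to_csv(path / "drugs.csv", index=False)
    pd.DataFrame(
        {"id": list(dataset.proteins), "sequence": list(dataset.proteins.values())}
    ).to_csv(path / "proteins.csv", index=False)
    pd.DataFrame(
        dataset.triples, columns=["drug_id", "protein_id", "value"]
    ).to_csv(path / "affinities.csv", index=False)
    if dataset.folds is not None:
        (path / "folds.json").write_text(json.dumps({"labels": list(dataset.folds)}))


def split_folds(
    dataset: AffinityDataset,
    k: int = 5,
    test_fraction: float = 1 / 6,
    seed: int = 0,
) -> AffinityDataset:
    """Assign each triple to a held-out test split or one of ``k`` CV folds.

    A seeded permutation first reserves ``round(n * test_fraction)`` triples
    as the fixed test set; the remainder is dealt round-robin into ``k``
    folds, so fold sizes differ by at most one.  The assignment is
    exhaustive, disjoint and deterministic under the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(dataset.triples)
    if n < k:
        raise ValueError(f"cannot split {n} triples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    labels: list[int | str] = [0] * n
    for rank, idx in enumerate(order):
        if rank < n_test:
            labels[idx] = TEST_LABEL
        else:
            labels[idx] = (rank - n_test) % k
    return replace(dataset, folds=tuple(labels))
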