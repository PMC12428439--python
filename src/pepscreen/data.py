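"""Labelled datasets, reproducible splits, and synthetic molecule generation.

The training material for the surrogate models is tabular: feature rows are
either the nine physicochemical descriptors or Morgan fingerprint bits, and
the targets are per-rule violation counts computed by the deterministic
counters in :mod:`pepscreen.rules`. Because the counters are the labelling
function, any descriptor table that covers the rule thresholds is a valid
training set; the descriptor-space sampler below generates such tables
directly, with optional stratification so that every violation class is
well represented.

A small peptide assembler turns residue sequences into linear peptide
SMILES (backbone fragments ``N[C@@H](R)C(=O)`` concatenated and capped with
a C-terminal hydroxyl), providing realistic peptide test molecules without
any external dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError, MissingDescriptorError, ParseError
from .molecules import (
    DESCRIPTOR_ESTIMATORS,
    DESCRIPTOR_KEYS,
    MoleculeRecord,
    compute_descriptors,
    morgan_fingerprint,
    parse_molecule,
)
from .rules import RuleSet, builtin_ruleset, count_violations_frame

# ---------------------------------------------------------------------------
# Containers


@dataclass
class LabelledDataset:
    """Aligned feature rows with per-rule violation-count targets."""

    representation: str  # "descriptors" | "fingerprints"
    feature_names: list[str]
    features: np.ndarray
    targets: dict[str, np.ndarray]
    ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.features)
        if len(self.ids) != n or any(len(t) != n for t in self.targets.values()):
            raise ValueError("features, targets and ids must have equal row counts")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix width does not match feature_names")

    @property
    def n(self) -> int:
        return len(self.features)

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.features, columns=self.feature_names)

    def subset(self, indices: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(
            representation=self.representation,
            feature_names=list(self.feature_names),
            features=self.features[indices],
            targets={k: v[indices] for k, v in self.targets.items()},
            ids=self.ids[indices],
            provenance=dict(self.provenance),
        )

    # -- CSV round trip -----------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        """Write ``id, <features...>, y_<rule>...`` plus a JSON provenance sidecar.

        Fingerprint rows are stored as packed hex strings to keep files small.
        """
        path = Path(path)
        df = pd.DataFrame({"id": self.ids})
        if self.representation == "fingerprints":
            packed = np.packbits(self.features.astype(np.uint8), axis=1)
            df["fp_hex"] = [row.tobytes().hex() for row in packed]
        else:
            for j, name in enumerate(self.feature_names):
                df[name] = self.features[:, j]
        for rule, y in self.targets.items():
            df[f"y_{rule}"] = y
        df.to_csv(path, index=False, float_format="%.12g")
        sidecar = dict(self.provenance)
        sidecar.update(
            representation=self.representation,
            feature_names=self.feature_names,
            n_rows=self.n,
        )
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabelledDataset":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".meta.json")
        provenance = (
            json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        )
        representation = provenance.get("representation", "descriptors")
        feature_names = provenance.get("feature_names")
        df = pd.read_csv(path)
        target_cols = [c for c in df.columns if c.startswith("y_")]
        targets = {c[2:]: df[c].to_numpy(dtype=np.int64) for c in target_cols}
        if representation == "fingerprints":
            n_bits = len(feature_names)
            packed = np.stack(
                [np.frombuffer(bytes.fromhex(h), dtype=np.uint8) for h in df["fp_hex"]]
            )
            features = np.unpackbits(packed, axis=1)[:, :n_bits]
        else:
            if feature_names is None:
                feature_names = [c for c in df.columns if c not in ("id", *target_cols)]
            features = df[feature_names].to_numpy(dtype=float)
        return cls(
            representation=representation,
            feature_names=list(feature_names),
            features=features,
            targets=targets,
            ids=df["id"].to_numpy(dtype=str),
            provenance={k: v for k, v in provenance.items() if k not in ("feature_names", "representation", "n_rows")},
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters (scikit-learn ``train_test_split`` semantics)."""

    test_fraction: float = 0.2
    seed: int = 42


@dataclass
class SamplerConfig:
    """Configuration of the descriptor-space sampler.

    ``ranges`` maps descriptor keys to ``(low, high)`` sampling intervals;
    integer-valued descriptors are drawn as inclusive integer uniforms. With
    ``stratify_rule`` set, sampling continues until every violation class
    ``0..max`` holds at least ``n // (2 * (max + 1))`` rows.
    """

    n: int
    seed: int = 0
    ranges: dict[str, tuple[float, float]] | None = None
    stratify_rule: str | None = None
    stratify_ruleset: RuleSet | None = None
    batch_size: int | None = None
    max_batches: int = 500

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("sampler n must be >= 0")


#: Default per-descriptor sampling intervals. Wide enough to straddle every
#: threshold of all three rule sets with generous margin on both sides.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mw": (50.0, 2000.0),
    "logp": (-8.0, 12.0),
    "hbd": (0, 30),
    "hba": (0, 40),
    "tpsa": (0.0, 600.0),
    "n_rotb": (0, 50),
    "n_carbon": (1, 120),
    "n_hetero": (0, 60),
    "n_rings": (0, 12),
}

_INTEGER_KEYS = frozenset({"hbd", "hba", "n_rotb", "n_carbon", "n_hetero", "n_rings"})


def _draw_batch(rng: np.random.Generator, n: int, ranges: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    cols = {}
    for key in DESCRIPTOR_KEYS:
        lo, hi = ranges[key]
        if key in _INTEGER_KEYS:
            cols[key] = rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
        else:
            cols[key] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(cols, columns=list(DESCRIPTOR_KEYS))


def sample_descriptor_vectors(cfg: SamplerConfig) -> pd.DataFrame:
    """Draw a descriptor table from independent per-descriptor uniforms.

    Deterministic for a fixed config. With stratification the table is
    assembled as per-class blocks (classes 0..max) followed by a block drawn
    from the unconstrained stream, so minimum class counts are guaranteed
    while the remainder keeps the sampler's natural class distribution.
    """
    ranges = dict(DEFAULT_RANGES)
    if cfg.ranges:
        ranges.update(cfg.ranges)
    missing = [k for k in DESCRIPTOR_KEYS if k not in ranges]
    if missing:
        raise ConfigurationError(f"sampler ranges missing descriptors: {missing}")
    rng = np.random.default_rng(cfg.seed)

    if cfg.n == 0:
        return pd.DataFrame(columns=list(DESCRIPTOR_KEYS))

    if cfg.stratify_rule is None and cfg.stratify_ruleset is None:
        return _draw_batch(rng, cfg.n, ranges)

    rs = cfg.stratify_ruleset or builtin_ruleset(cfg.stratify_rule)
    k = rs.max_violations
    per_class_min = cfg.n // (2 * (k + 1))
    general_quota = cfg.n - (k + 1) * per_class_min
    batch_size = cfg.batch_size or min(max(cfg.n, 100_000), 2_000_000)

    class_pools: list[list[pd.DataFrame]] = [[] for _ in range(k + 1)]
    class_counts = np.zeros(k + 1, dtype=int)
    general_pool: list[pd.DataFrame] = []
    general_count = 0

    for _ in range(cfg.max_batches):
        batch = _draw_batch(rng, batch_size, ranges)
        labels = count_violations_frame(batch, rs)
        if general_count < general_quota:
            take = min(general_quota - general_count, len(batch))
            general_pool.append(batch.iloc[:take])
            general_count += take
        for c in range(k + 1):
            if class_counts[c] >= per_class_min:
                continue
            rows = batch[labels == c]
            take = min(per_class_min - class_counts[c], len(rows))
            if take:
                class_pools[c].append(rows.iloc[:take])
                class_counts[c] += take
        if general_count >= general_quota and (class_counts >= per_class_min).all():
            parts = [df for pool in class_pools for df in pool] + general_pool
            return pd.concat(parts, ignore_index=True)

    short = [c for c in range(k + 1) if class_counts[c] < per_class_min]
    raise ConfigurationError(
        f"stratified sampling could not reach {per_class_min} rows for classes "
        f"{short} of rule {rs.name!r} within {cfg.max_batches} batches; "
        "widen the sampling ranges or raise max_batches"
    )


# ---------------------------------------------------------------------------
# Dataset builders


def _ruleset_provenance(rulesets: Sequence[RuleSet]) -> dict:
    return {
        rs.name: {"variant": rs.variant, "fingerprint": rs.thresholds_fingerprint()}
        for rs in rulesets
    }


def build_dataset_from_descriptor_table(
    table: pd.DataFrame,
    rulesets: Sequence[RuleSet],
    ids: Sequence[str] | None = None,
    provenance: dict | None = None,
) -> LabelledDataset:
    """Label a descriptor table with every rule's violation counter."""
    if len(table) == 0:
        raise ConfigurationError("descriptor table is empty")
    targets = {rs.name: count_violations_frame(table, rs) for rs in rulesets}
    feature_names = [c for c in DESCRIPTOR_KEYS if c in table.columns]
    referenced = {c.descriptor_key for rs in rulesets for c in rs.criteria}
    missing = referenced - set(feature_names)
    if missing:
        raise MissingDescriptorError(f"descriptor table lacks columns {sorted(missing)}")
    if ids is None:
        ids = np.array([f"row{i:07d}" for i in range(len(table))])
    prov = dict(provenance or {})
    prov.setdefault("rulesets", _ruleset_provenance(rulesets))
    prov.setdefault("descriptor_estimators", DESCRIPTOR_ESTIMATORS)
    return LabelledDataset(
        representation="descriptors",
        feature_names=feature_names,
        features=table[feature_names].to_numpy(dtype=float),
        targets=targets,
        ids=np.asarray(ids, dtype=str),
        provenance=prov,
    )


def build_labelled_dataset(
    molecules: Sequence[MoleculeRecord],
    rulesets: Sequence[RuleSet],
    representation: str = "descriptors",
    fp_params: tuple[int, int] = (2, 2048),
) -> LabelledDataset:
    """Build a dataset from molecules.

    Targets are always computed from the molecule's descriptor vector —
    fingerprint rows carry the same labels as their descriptor counterparts.
    Parse failures are collected into provenance (and warned about), never
    silently dropped; if every molecule fails, an error lists the reasons.
    """
    if not molecules:
        raise ConfigurationError("no molecules supplied")
    if representation not in ("descriptors", "fingerprints"):
        raise ConfigurationError(f"unknown representation {representation!r}")
    desc_rows, fp_rows, ids, failures = [], [], [], []
    radius, n_bits = fp_params
    for rec in molecules:
        try:
            mol = parse_molecule(rec.smiles, rec.id)
            dv = compute_descriptors(mol, rec.id)
        except ParseError as exc:
            failures.append({"id": rec.id, "reason": str(exc)})
            continue
        desc_rows.append(dv.as_dict())
        if representation == "fingerprints":
            fp_rows.append(morgan_fingerprint(mol, radius, n_bits).bits)
        ids.append(rec.id)
    if not desc_rows:
        raise ParseError(
            "all molecules failed to parse: "
            + "; ".join(f"{f['id']}: {f['reason']}" for f in failures)
        )
    if failures:
        warnings.warn(f"{len(failures)} molecule(s) failed to parse and were excluded")
    desc_table = pd.DataFrame(desc_rows, columns=list(DESCRIPTOR_KEYS))
    targets = {rs.name: count_violations_frame(desc_table, rs) for rs in rulesets}
    prov = {
        "rulesets": _ruleset_provenance(rulesets),
        "descriptor_estimators": DESCRIPTOR_ESTIMATORS,
        "parse_failures": failures,
    }
    if representation == "fingerprints":
        prov["fingerprint_params"] = {"radius": radius, "n_bits": n_bits}
        return LabelledDataset(
            representation="fingerprints",
            feature_names=[f"bit{j}" for j in range(n_bits)],
            features=np.stack(fp_rows),
            targets=targets,
            ids=np.asarray(ids, dtype=str),
            provenance=prov,
        )
    return LabelledDataset(
        representation="descriptors",
        feature_names=list(DESCRIPTOR_KEYS),
        features=desc_table.to_numpy(dtype=float),
        targets=targets,
        ids=np.asarray(ids, dtype=str),
        provenance=prov,
    )


def split_dataset(
    ds: LabelledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[LabelledDataset, LabelledDataset]:
    """Disjoint train/test partition with ``|test| = round(n * test_fraction)``."""
    if not 0 < spec.test_fraction < 1:
        raise ConfigurationError(f"test_fraction must be in (0, 1), got {spec.test_fraction}")
    n_test = int(round(ds.n * spec.test_fraction))
    if n_test < 1 or ds.n - n_test < 1:
        raise ConfigurationError(
            f"cannot split {ds.n} rows into non-empty train and test at fraction {spec.test_fraction}"
        )
    idx_train, idx_test = train_test_split(
        np.arange(ds.n), test_size=n_test, random_state=spec.seed, shuffle=True
    )
    train, test = ds.subset(idx_train), ds.subset(idx_test)
    for part in (train, test):
        part.provenance["split"] = {"test_fraction": spec.test_fraction, "seed": spec.seed}
    return train, test


# ---------------------------------------------------------------------------
# Peptide assembly

#: Backbone fragments of the 20 proteinogenic residues, shaped so that plain
#: string concatenation forms the peptide bond; the chain is capped with a
#: C-terminal hydroxyl.
AMINO_ACIDS: dict[str, str] = {
    "G": "NCC(=O)",
    "A": "N[C@@H](C)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "P": "N1CCC[C@H]1C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@@H](O)C)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "D": "N[C@@H](CC(O)=O)C(=O)",
    "E": "N[C@@H](CCC(O)=O)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "R": "N[C@@H](CCCNC(N)=N)C(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
}


def peptide_smiles(sequence: str, alphabet: Mapping[str, str] | None = None) -> str:
    """Assemble a linear peptide SMILES from a one-letter residue sequence."""
    alphabet = alphabet or AMINO_ACIDS
    fragments = []
    for code in sequence:
        if code not in alphabet:
            raise ConfigurationError(f"unknown residue code {code!r}")
        fragments.append(alphabet[code])
    if not fragments:
        raise ConfigurationError("empty residue sequence")
    return "".join(fragments) + "O"


def generate_peptide_smiles(
    length: int,
    alphabet: Mapping[str, str] | None = None,
    seed: int = 0,
) -> MoleculeRecord:
    """Generate a random linear peptide of ``length`` residues.

    The output is guaranteed parseable. Residues are drawn uniformly from the
    alphabet (default: the 20 proteinogenic amino acids).
    """
    if length < 1:
        raise ConfigurationError("peptide length must be >= 1")
    alphabet = alphabet or AMINO_ACIDS
    rng = np.random.default_rng(seed)
    codes = sorted(alphabet)
    sequence = "".join(rng.choice(codes) for _ in range(length))
    smiles = peptide_smiles(sequence, alphabet)
    rec = MoleculeRecord(id=f"pep-{seed}-{length}", smiles=smiles, name=sequence)
    parse_molecule(rec.smiles, rec.id)  # assembly contract: always parseable
    return rec
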