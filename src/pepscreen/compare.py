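"""Agreement accounting between model predictions and reference counts.

Reference violation counts typically come from web platform exports
(SwissADME, Molinspiration) or manual calculation. Platforms fail on some
inputs — long peptide SMILES in particular — so reference cells may be
missing; missing cells are excluded from that source's denominator, never
imputed. The report tracks exact matches, off-by-one cases, and a signed
delta histogram so systematic +/-1 biases are visible at a glance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass
class ComparisonRow:
    id: str
    predictions: dict[str, int]            # prediction column -> count
    references: dict[str, int | None]      # source -> count or None (missing)
    deltas: dict[tuple[str, str], int]     # (source, prediction column) -> pred - ref
    exact_match: dict[tuple[str, str], bool]


@dataclass
class ComparisonReport:
    rule: str
    rows: list[ComparisonRow]
    summary: dict[tuple[str, str], dict]   # (source, prediction column) -> counts
    delta_histogram: dict[tuple[str, str], dict[int, int]]

    def summary_frame(self) -> pd.DataFrame:
        records = []
        for (source, pred_col), counts in sorted(self.summary.items()):
            records.append({"source": source, "prediction": pred_col, **counts})
        return pd.DataFrame(records)

    def rows_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec: dict = {"id": row.id, **row.predictions}
            for source, val in row.references.items():
                rec[f"ref_{source}"] = val
            for (source, pred_col), delta in row.deltas.items():
                rec[f"delta_{source}_{pred_col}"] = delta
            records.append(rec)
        return pd.DataFrame(records)

    def to_json(self) -> str:
        payload = {
            "rule": self.rule,
            "summary": {
                f"{source}|{pred}": counts for (source, pred), counts in sorted(self.summary.items())
            },
            "delta_histogram": {
                f"{source}|{pred}": {str(d): c for d, c in sorted(hist.items())}
                for (source, pred), hist in sorted(self.delta_histogram.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def load_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference CSV: ``id`` plus one integer column per source.

    Empty cells and ``NaN`` denote unavailable references and are kept
    missing (nullable integers), never coerced to 0. Duplicate ids error.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ConfigurationError(f"{path}: reference CSV must contain an 'id' column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ConfigurationError(f"duplicate reference ids: {dupes}")
    df = df.set_index("id")
    for col in df.columns:
        df[col] = pd.array(np.floor(pd.to_numeric(df[col], errors="coerce")), dtype="Int64")
    return df


def compare_predictions(
    preds: pd.DataFrame,
    refs: pd.DataFrame,
    rule: str,
    rule_metadata: str | None = None,
) -> ComparisonReport:
    """Compare per-molecule predictions with per-source references.

    ``preds`` must carry an ``id`` column and one integer column per model
    configuration (e.g. ``classifier_10``). Every prediction id must be
    present; reference coverage may be partial. ``rule_metadata``, when
    given, must match ``rule`` (guards against comparing counts produced
    under different rules).
    """
    if rule_metadata is not None and rule_metadata != rule:
        raise ConfigurationError(
            f"rule mismatch: predictions are for {rule_metadata!r}, references for {rule!r}"
        )
    if "id" not in preds.columns:
        raise ConfigurationError("prediction table must contain an 'id' column")
    pred_cols = [c for c in preds.columns if c != "id"]
    sources = list(refs.columns)

    rows: list[ComparisonRow] = []
    tallies: dict[tuple[str, str], dict] = {
        (s, p): {"n_compared": 0, "n_exact": 0, "n_off_by_one": 0, "n_missing": 0}
        for s in sources
        for p in pred_cols
    }
    hist: dict[tuple[str, str], dict[int, int]] = {
        (s, p): {} for s in sources for p in pred_cols
    }

    for rec in preds.itertuples(index=False):
        mol_id = rec.id
        predictions = {p: int(getattr(rec, p)) for p in pred_cols}
        references: dict[str, int | None] = {}
        deltas: dict[tuple[str, str], int] = {}
        exact: dict[tuple[str, str], bool] = {}
        for source in sources:
            ref_val = refs.at[mol_id, source] if mol_id in refs.index else pd.NA
            if pd.isna(ref_val):
                references[source] = None
                for p in pred_cols:
                    tallies[(source, p)]["n_missing"] += 1
                continue
            ref_val = int(ref_val)
            references[source] = ref_val
            for p in pred_cols:
                delta = predictions[p] - ref_val
                deltas[(source, p)] = delta
                exact[(source, p)] = delta == 0
                t = tallies[(source, p)]
                t["n_compared"] += 1
                if delta == 0:
                    t["n_exact"] += 1
                elif abs(delta) == 1:
                    t["n_off_by_one"] += 1
                h = hist[(source, p)]
                h[delta] = h.get(delta, 0) + 1
        rows.append(
            ComparisonRow(
                id=str(mol_id),
                predictions=predictions,
                references=references,
                deltas=deltas,
                exact_match=exact,
            )
        )
    return ComparisonReport(rule=rule, rows=rows, summary=tallies, delta_histogram=hist)
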