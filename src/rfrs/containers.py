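"""In-memory containers for expression and clinical data.

An :class:`ExpressionMatrix` holds normalized, linear-scale intensities
(samples x features) together with a feature -> gene-symbol map.  A
:class:`ClinicalTable` holds per-sample outcome and annotation columns.
Both round-trip through plain tab-delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = [
    "sample_id",
    "study_id",
    "er_clinical",
    "her2_clinical",
    "ln_status",
    "chemo",
    "hormone_therapy",
    "relapse_event",
    "followup_years",
]

MISSING = "missing"


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass
class ExpressionMatrix:
    """Samples x features matrix of positive linear-scale intensities.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by sample id, columns by feature (probe set) id.
        All entries must be finite and strictly positive (linear scale,
        i.e. before any log transform).
    feature_to_gene : dict
        Maps each feature id to a gene symbol.  Features absent from the
        map are treated as their own gene.
    """

    values: pd.DataFrame
    feature_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise InputError(f"duplicated sample identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise InputError(f"duplicated feature identifiers: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InputError("expression values must be finite")
        if np.any(arr <= 0):
            raise InputError("expression values must be strictly positive (linear scale)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def gene_of(self, feature_id: str) -> str:
        return self.feature_to_gene.get(feature_id, feature_id)

    def log2(self) -> pd.DataFrame:
        """Log2-transformed copy of the values (used for correlations)."""
        return np.log2(self.values)

    def subset(self, samples=None, features=None) -> "ExpressionMatrix":
        vals = self.values
        if samples is not None:
            vals = vals.loc[list(samples)]
        if features is not None:
            missing = [f for f in features if f not in vals.columns]
            if missing:
                raise InputError(f"features not present: {missing}")
            vals = vals[list(features)]
        f2g = {f: self.feature_to_gene[f] for f in vals.columns if f in self.feature_to_gene}
        return ExpressionMatrix(vals.copy(), f2g)

    # -- tab-delimited round trip ------------------------------------

    def to_tsv(self, path: str | Path, gene_map_path: str | Path | None = None) -> None:
        path = Path(path)
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.6g")
        if gene_map_path is not None:
            pd.DataFrame(
                {"feature_id": list(self.feature_to_gene), "gene": list(self.feature_to_gene.values())}
            ).to_csv(gene_map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, gene_map_path: str | Path | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        f2g: dict[str, str] = {}
        if gene_map_path is not None:
            gm = pd.read_csv(gene_map_path, sep="\t")
            f2g = dict(zip(gm["feature_id"].astype(str), gm["gene"].astype(str)))
        return cls(df, f2g)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    Columns: sample_id, study_id, er_clinical / her2_clinical in
    {'+', '-', 'missing'}, ln_status in {'negative', 'positive',
    'missing'}, boolean chemo / hormone_therapy / relapse_event, and
    followup_years (time of relapse if relapse_event else last
    follow-up, in years).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise InputError(f"clinical table missing columns: {missing_cols}")
        df = self.data.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise InputError("duplicated sample_id in clinical table")
        for col in ("chemo", "hormone_therapy", "relapse_event"):
            df[col] = df[col].astype(bool)
        df["followup_years"] = df["followup_years"].astype(float)
        if (df["followup_years"] < 0).any():
            raise InputError("followup_years must be nonnegative")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def loc(self, sample_ids) -> "ClinicalTable":
        idx = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(idx)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        for col in ("er_clinical", "her2_clinical", "ln_status"):
            df[col] = df[col].fillna(MISSING).astype(str)
        return cls(df)
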