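"""Exon/junction usage normalization (the splicing index).

Given a gene's exon or junction quantification matrix ``x`` (features i = 1..n
by samples j = 1..m, non-negative), the per-sample gene expression is the mean
over features,

    e_j = (1/n) * sum_i x_ij,

each value is divided by e_j to remove the gene-expression effect, and the
resulting ratio is rescaled by the feature's 95th percentile across samples so
outliers do not compress the display range:

    y_ij = min( x_ij / (e_j * Q95_i), 1 )    if Q95_i > 0.05
    y_ij = min( x_ij / (e_j * 0.05),  1 )    if Q95_i <= 0.05

The 0.05 floor keeps features whose signal is tiny relative to the gene from
being blown up to full scale.  All defined y lie in [0, 1].  Q95_i is the 95th
percentile (linear interpolation between order statistics) of the normalized
ratios r_ij = x_ij / e_j; samples with e_j = 0 produce r_ij = 0 and are
flagged rather than NaN.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

USAGE_FLOOR = 0.05
Q95_PROB = 95.0

VALID_KINDS = ("exon", "junction", "isoform", "gene")


@dataclass
class QuantMatrix:
    """Features x samples non-negative quantification matrix (x_ij)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str = "exon"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if np.isnan(self.values).any():
            raise ValueError("missing values not permitted; handle at load")
        if (self.values < 0).any():
            raise ValueError("quantification values must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "exon") -> "QuantMatrix":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            kind=kind,
        )

    def subset_features(self, feature_ids: list[str]) -> "QuantMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return QuantMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            kind=self.kind,
        )


@dataclass
class GeneExpressionVector:
    """Per-sample gene expression e_j, estimated from the feature matrix."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("values must align with sample_ids")
        if (self.values < 0).any():
            raise ValueError("gene expression must be non-negative")


@dataclass
class UsageMatrix:
    """Normalized usage values y_ij in [0, 1] with the Q95 scale recorded."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    q95: np.ndarray
    floor: float = USAGE_FLOOR
    zero_expression_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.q95 = np.asarray(self.q95, dtype=float)
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("usage values must lie in [0, 1]")
        if (self.q95 < 0).any():
            raise ValueError("q95 must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class LoadReport:
    n_features: int
    n_samples: int
    n_missing_imputed: int = 0
    n_rows_dropped: int = 0


def read_quant_tsv(path, kind: str, missing: str = "zero") -> tuple[QuantMatrix, LoadReport]:
    """Load a quantification TSV (first column feature_id, one column per sample).

    ``missing`` controls NaN handling: "zero" imputes 0 with a warning count,
    "drop" removes the affected rows.  gzip input is accepted by extension.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    n_missing = int(df.isna().to_numpy().sum())
    n_dropped = 0
    if n_missing:
        if missing == "zero":
            df = df.fillna(0.0)
            warnings.warn(f"imputed {n_missing} missing values to 0", stacklevel=2)
        elif missing == "drop":
            before = len(df)
            df = df.dropna(axis=0)
            n_dropped = before - len(df)
        else:
            raise ValueError("missing must be 'zero' or 'drop'")
    qm = QuantMatrix.from_dataframe(df, kind=kind)
    return qm, LoadReport(
        n_features=qm.n_features,
        n_samples=qm.n_samples,
        n_missing_imputed=n_missing if missing == "zero" else 0,
        n_rows_dropped=n_dropped,
    )


def gene_expression(x: QuantMatrix) -> GeneExpressionVector:
    """e_j: column mean of the gene's annotated features."""
    if x.n_features == 0:
        raise ValueError("no annotated features")
    return GeneExpressionVector(
        sample_ids=list(x.sample_ids), values=x.values.mean(axis=0)
    )


def ratio_matrix(
    x: QuantMatrix, e: GeneExpressionVector
) -> tuple[np.ndarray, list[str]]:
    """r_ij = x_ij / e_j; zero-expression samples yield 0 and are flagged."""
    if list(x.sample_ids) != list(e.sample_ids):
        raise ValueError("sample IDs of x and e do not align")
    zero = e.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(zero[None, :], 0.0, x.values / np.where(zero, 1.0, e.values))
    flagged = [s for s, z in zip(x.sample_ids, zero) if z]
    return r, flagged


def q95_per_feature(r: np.ndarray) -> np.ndarray:
    """Per-feature 95th percentile across samples (linear interpolation)."""
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] < 1 or r.shape[1] < 1:
        raise ValueError("ratio matrix must be non-empty 2-D")
    return np.percentile(r, Q95_PROB, axis=1, method="linear")


def usage(x: QuantMatrix) -> UsageMatrix:
    """Compute the usage matrix y from a gene's quantification matrix x."""
    e = gene_expression(x)
    r, flagged = ratio_matrix(x, e)
    q95 = q95_per_feature(r)
    scale = np.maximum(q95, USAGE_FLOOR)
    y = np.minimum(r / scale[:, None], 1.0)
    return UsageMatrix(
        feature_ids=list(x.feature_ids),
        sample_ids=list(x.sample_ids),
        values=y,
        q95=q95,
        floor=USAGE_FLOOR,
        zero_expression_samples=flagged,
    )


def write_usage_tsv(u: UsageMatrix, path, sidecar_path=None) -> None:
    """Write usage values as TSV plus a {feature_id: q95} JSON sidecar."""
    u.to_dataframe().to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {f: float(q) for f, q in zip(u.feature_ids, u.q95)},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
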