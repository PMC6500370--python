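"""Reading, validating and aligning expression / methylation matrices.

Expression matrices are genes x samples, log-scale normalized values.
Methylation matrices are CpG probes x samples, on either the beta scale
(proportion methylated, in [0, 1]) or the M scale (log2(beta/(1-beta)),
unbounded).  Both are read from plain TSV or from the GEO series-matrix
dialect (``!``-prefixed metadata lines, quoted identifiers, an optional
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` fence).

Missing methylation entries (empty cells or ``NA``) are retained as NaN at
load time; they are handled per gene downstream by listwise deletion, never
imputed.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MatrixParseError",
    "MatrixValidationError",
    "ExpressionMatrix",
    "MethylationMatrix",
    "PairedDataset",
    "read_expression_matrix",
    "read_methylation_matrix",
    "beta_to_m",
    "m_to_beta",
    "align_samples",
    "write_matrix",
    "read_matrix",
]

#: smallest beta value kept before the logit2 transform
DEFAULT_CLIP_EPS = 1e-6

#: minimum number of paired samples for cross-validation to make sense
MIN_PAIRED_SAMPLES = 10


class MatrixParseError(ValueError):
    """File could not be parsed into a matrix."""


class MatrixValidationError(ValueError):
    """Parsed matrix violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Log-scale normalized expression, one row per gene symbol."""

    values: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise MatrixValidationError(f"duplicate gene id {dup!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise MatrixValidationError(f"duplicate sample id {dup!r}")
        finite = np.isfinite(self.values.to_numpy(dtype=float))
        if not finite.any(axis=1).all():
            gene = idx[~finite.any(axis=1)][0]
            raise MatrixValidationError(f"gene {gene!r} has no finite value")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationMatrix:
    """Per-probe methylation, beta or M scale; NaN marks missing entries."""

    values: pd.DataFrame  # probes x samples
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise MatrixValidationError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise MatrixValidationError(f"duplicate probe id {dup!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise MatrixValidationError(f"duplicate sample id {dup!r}")
        if self.scale == "beta":
            vals = self.values.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MatrixValidationError(
                    f"beta value {vals[i, j]} out of [0, 1] at probe "
                    f"{idx[i]!r}, sample {cols[j]!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class PairedDataset:
    """Expression and methylation restricted to a common, ordered sample set."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = self.expression.sample_ids
        if self.expression.sample_ids != self.sample_ids:
            raise MatrixValidationError("expression samples differ from pair order")
        if self.methylation.sample_ids != self.sample_ids:
            raise MatrixValidationError("methylation samples differ from pair order")
        if len(self.sample_ids) < MIN_PAIRED_SAMPLES:
            raise MatrixValidationError(
                f"only {len(self.sample_ids)} paired samples; "
                f"need at least {MIN_PAIRED_SAMPLES}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read a row-id + sample-header table in either supported dialect."""
    path = Path(path)
    if dialect not in ("plain_tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    if dialect == "series_matrix":
        lines = text.splitlines()
        if any(l.startswith("!series_matrix_table_begin") for l in lines):
            inside = False
            kept = []
            for line in lines:
                if line.startswith("!series_matrix_table_begin"):
                    inside = True
                    continue
                if line.startswith("!series_matrix_table_end"):
                    break
                if inside:
                    kept.append(line)
        else:
            kept = [l for l in lines if not l.startswith("!")]
        text = "\n".join(kept)
    # explicit duplicate check: pandas silently mangles repeated column names
    header_line = next(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#")), None
    )
    if header_line is None:
        raise MatrixParseError(f"{path}: no header line found")
    fields = [f.strip('"') for f in header_line.rstrip("\n").split("\t")]
    samples = fields[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise MatrixValidationError(f"{path}: duplicate sample id {dup!r} in header")
    try:
        df = pd.read_csv(
            _io.StringIO(text),
            sep="\t",
            index_col=0,
            comment="#",
            na_values=["NA", "null"],
            keep_default_na=True,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise MatrixParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip('"')
    df.index.name = None
    df.columns = df.columns.astype(str).str.strip('"')
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixParseError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def read_expression_matrix(
    path: str | Path, dialect: str = "plain_tsv"
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    Rows sharing a gene symbol (several array probesets mapping to one gene)
    are collapsed by per-sample mean, with a log record of how many were
    merged.
    """
    df = _read_table(path, dialect)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by per-sample mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)


def read_methylation_matrix(
    path: str | Path, scale: str = "beta", dialect: str = "plain_tsv"
) -> MethylationMatrix:
    """Read a probes x samples methylation TSV; NA/empty cells become NaN."""
    df = _read_table(path, dialect)
    mat = MethylationMatrix(df, scale=scale)
    if mat.n_missing:
        log.info("%s: %d missing methylation entries", path, mat.n_missing)
    return mat


def beta_to_m(beta, eps: float = DEFAULT_CLIP_EPS):
    """Logit2 transform: m = log2(beta / (1 - beta)).

    Values outside [eps, 1-eps] are clipped first (clipping is logged);
    operates elementwise on scalars, arrays and DataFrames.
    """
    arr = np.asarray(beta, dtype=float)
    n_clip = int(((arr < eps) | (arr > 1 - eps)).sum())
    if n_clip:
        log.info("beta_to_m: clipped %d values to [%g, %g]", n_clip, eps, 1 - eps)
    clipped = np.clip(arr, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2**m / (1 + 2**m)."""
    arr = np.asarray(m, dtype=float)
    # numerically stable on both tails
    beta = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)), 2.0**arr / (1.0 + 2.0**arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if np.isscalar(m):
        return float(beta)
    return beta


def align_samples(
    expr: ExpressionMatrix, meth: MethylationMatrix
) -> PairedDataset:
    """Restrict both matrices to their common samples, in expression order.

    Mirrors cohorts where more individuals have expression than methylation
    data (or vice versa); requires at least ``MIN_PAIRED_SAMPLES`` overlap.
    """
    meth_set = set(meth.sample_ids)
    common = [s for s in expr.sample_ids if s in meth_set]
    if not common:
        raise MatrixValidationError("expression and methylation share no samples")
    if len(common) < MIN_PAIRED_SAMPLES:
        raise MatrixValidationError(
            f"only {len(common)} shared samples; need at least {MIN_PAIRED_SAMPLES}"
        )
    expr_sub = ExpressionMatrix(expr.values.loc[:, common])
    meth_sub = MethylationMatrix(meth.values.loc[:, common], scale=meth.scale)
    return PairedDataset(expr_sub, meth_sub, common)


def write_matrix(
    values: pd.DataFrame, path: str | Path, header_note: str | None = None
) -> None:
    """Write a matrix as TSV with an optional '# '-prefixed header comment."""
    path = Path(path)
    with path.open("w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        values.to_csv(fh, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read back a matrix written by :func:`write_matrix`."""
    return _read_table(path, "plain_tsv")
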