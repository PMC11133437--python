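"""End-to-end QSPR study: descriptor table -> correlations, 42 models,
predicted-vs-actual tables, rendered reports.

The study regresses each of six physico-chemical properties on each of the
seven topological indices (one simple model per pair, 42 in all), exactly
as a descriptor screening is reported: a 7 x 6 Pearson correlation matrix,
a per-index statistics panel (A, B, r, r^2, S.E, F, P), and per-property
tables comparing measured values with every model's prediction.

Predicted-vs-actual tables default to applying the *published* equation —
coefficients rounded to 4 decimals — because that is how a reported model
``Y = A + B X`` is used by a reader (and how the reference tables were
generated); pass ``coef_digits=None`` for full-precision predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .indices import INDEX_NAMES, compute_all
from .molgraph import MolecularGraph
from .regress import RegressionFit, fit_ols, pearson_r, round_half_away

__all__ = [
    "PROPERTY_NAMES",
    "QsprReport",
    "build_descriptor_table",
    "load_property_table",
    "correlation_matrix",
    "fit_all_models",
    "prediction_tables",
    "render_report",
    "run_study",
]

#: The six property columns, fixed names and order (units in fixtures doc).
PROPERTY_NAMES: tuple[str, ...] = (
    "polarizability",
    "complexity",
    "boiling_point",
    "molecular_weight",
    "molar_volume",
    "flash_point",
)


def build_descriptor_table(
    source: Iterable[MolecularGraph] | str | Path | pd.DataFrame,
) -> pd.DataFrame:
    """Drug x index descriptor table, from graphs or from a CSV.

    Graph input computes every index per graph; CSV/DataFrame input takes
    the columns M1,M2,H,F,SS,ReZG2,ReZG3 verbatim (the mode to use when the
    analysis must follow a published descriptor table rather than
    re-derived values).
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, index_col=0)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        graphs = list(source)
        if not graphs:
            raise ValueError("no graphs given")
        names = [g.name for g in graphs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in graph list")
        df = pd.DataFrame(
            [compute_all(g).as_dict() for g in graphs], index=pd.Index(names, name="drug")
        )
    missing = [c for c in INDEX_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"descriptor table missing columns {missing}")
    if df.index.has_duplicates:
        raise ValueError("duplicate drug names in descriptor table")
    out = df.loc[:, list(INDEX_NAMES)].astype(float)
    _check_values(out, "descriptor")
    return out


def load_property_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Drug x property table with the six fixed columns.

    Extra columns are dropped with a warning; a missing column or a missing
    cell is an error (no imputation).
    """
    df = pd.read_csv(source, index_col=0) if isinstance(source, (str, Path)) else source.copy()
    missing = [c for c in PROPERTY_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing columns {missing}")
    extra = [c for c in df.columns if c not in PROPERTY_NAMES]
    if extra:
        warnings.warn(f"ignoring extra property columns {extra}", stacklevel=2)
    if df.index.has_duplicates:
        raise ValueError("duplicate drug names in property table")
    out = df.loc[:, list(PROPERTY_NAMES)].astype(float)
    _check_values(out, "property")
    return out


def _check_values(df: pd.DataFrame, what: str) -> None:
    if df.isna().any().any():
        bad = [(str(i), str(c)) for i, c in zip(*np.where(df.isna().to_numpy()))]
        raise ValueError(f"{what} table has missing values at {bad[:5]}")
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{what} table has non-finite values")


def _align(descriptors: pd.DataFrame, properties: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(descriptors.index) != set(properties.index):
        only_d = sorted(set(descriptors.index) - set(properties.index))
        only_p = sorted(set(properties.index) - set(descriptors.index))
        raise ValueError(
            f"tables are misaligned: descriptors-only {only_d}, properties-only {only_p}"
        )
    if len(descriptors) < 3:
        raise ValueError(f"need at least 3 drugs, got {len(descriptors)}")
    return descriptors, properties.loc[descriptors.index]


def correlation_matrix(
    descriptors: pd.DataFrame, properties: pd.DataFrame
) -> pd.DataFrame:
    """7 x 6 Pearson correlations, indices as rows, properties as columns."""
    d, p = _align(descriptors, properties)
    return pd.DataFrame(
        {
            prop: [pearson_r(d[i], p[prop]) for i in INDEX_NAMES]
            for prop in PROPERTY_NAMES
        },
        index=pd.Index(INDEX_NAMES, name="index"),
    )


def fit_all_models(
    descriptors: pd.DataFrame, properties: pd.DataFrame
) -> dict[tuple[str, str], RegressionFit]:
    """One OLS fit per (index, property) pair — 42 models."""
    d, p = _align(descriptors, properties)
    fits: dict[tuple[str, str], RegressionFit] = {}
    for i in INDEX_NAMES:
        for prop in PROPERTY_NAMES:
            try:
                fits[(i, prop)] = fit_ols(d[i].to_numpy(), p[prop].to_numpy())
            except ValueError as err:
                raise ValueError(f"fit failed for pair ({i}, {prop}): {err}") from err
    return fits


def prediction_tables(
    fits: Mapping[tuple[str, str], RegressionFit],
    descriptors: pd.DataFrame,
    properties: pd.DataFrame,
    *,
    coef_digits: int | None = 4,
) -> dict[str, pd.DataFrame]:
    """Per-property table of measured value and all seven model predictions.

    ``coef_digits`` rounds the coefficients before applying the line (the
    published-equation convention, default); ``None`` uses full precision.
    """
    d, p = _align(descriptors, properties)
    out: dict[str, pd.DataFrame] = {}
    for prop in PROPERTY_NAMES:
        cols: dict[str, object] = {"actual": p[prop]}
        for i in INDEX_NAMES:
            fit = fits[(i, prop)]
            if coef_digits is not None:
                fit = fit.round(coef_digits)
            cols[i] = [fit.predict(x) for x in d[i]]
        out[prop] = pd.DataFrame(cols, index=d.index)
    return out


@dataclass(frozen=True)
class QsprReport:
    """Complete study output: correlations, fits, prediction tables."""

    correlations: pd.DataFrame
    fits: dict[tuple[str, str], RegressionFit]
    predictions: dict[str, pd.DataFrame]

    def model_panel(self, index: str) -> pd.DataFrame:
        """A, B, r, r2, S.E, F, P panel of one index across all properties."""
        rows = []
        for prop in PROPERTY_NAMES:
            ft = self.fits[(index, prop)]
            rows.append(
                {"property": prop, "A": ft.a, "B": ft.b, "r": ft.r,
                 "r2": ft.r2, "SE": ft.se, "F": ft.f, "P": ft.p}
            )
        return pd.DataFrame(rows).set_index("property")


def run_study(
    descriptors: pd.DataFrame,
    properties: pd.DataFrame,
    *,
    coef_digits: int | None = 4,
) -> QsprReport:
    """Assemble the full report from aligned descriptor/property tables."""
    corr = correlation_matrix(descriptors, properties)
    fits = fit_all_models(descriptors, properties)
    preds = prediction_tables(fits, descriptors, properties, coef_digits=coef_digits)
    # internal consistency: the matrix must agree with the per-pair fits
    for i in INDEX_NAMES:
        for prop in PROPERTY_NAMES:
            assert abs(corr.loc[i, prop] - fits[(i, prop)].r) < 1e-9
    return QsprReport(correlations=corr, fits=fits, predictions=preds)


def render_report(
    report: QsprReport,
    destination: str | Path,
    *,
    digits: int = 4,
    indices: Sequence[str] = INDEX_NAMES,
) -> list[Path]:
    """Write the report as CSV files plus one Markdown summary.

    Produces ``correlations.csv``, ``model_<index>.csv`` per index,
    ``predictions_<property>.csv`` per property and ``report.md``. All
    numbers rounded half-away-from-zero to ``digits`` decimals; output is
    deterministic (two runs give byte-identical files).
    """
    if not report.fits:
        raise ValueError("empty report")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    rnd = lambda df: df.map(lambda v: round_half_away(v, digits))
    written: list[Path] = []

    def _write(df: pd.DataFrame, fname: str) -> None:
        path = dest / fname
        rnd(df).to_csv(path, float_format=f"%.{digits}f")
        written.append(path)

    _write(report.correlations, "correlations.csv")
    for i in indices:
        _write(report.model_panel(i), f"model_{i}.csv")
    for prop in PROPERTY_NAMES:
        _write(report.predictions[prop], f"predictions_{prop}.csv")

    def _md(df: pd.DataFrame) -> str:
        cells = rnd(df)
        header = [str(cells.index.name or "")] + [str(c) for c in cells.columns]
        rows = [[str(i)] + [f"{v:.{digits}f}" for v in cells.loc[i]] for i in cells.index]
        widths = [max(len(r[k]) for r in [header] + rows) for k in range(len(header))]
        fmt = lambda r: "| " + " | ".join(s.rjust(w) for s, w in zip(r, widths)) + " |"
        sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
        return "\n".join([fmt(header), sep] + [fmt(r) for r in rows])

    lines = ["# QSPR report", "", "## Correlation matrix", "",
             _md(report.correlations), ""]
    for i in indices:
        lines += [f"## Models of {i}", "", _md(report.model_panel(i)), ""]
        for prop in PROPERTY_NAMES:
            lines.append(
                "- " + report.fits[(i, prop)].equation(prop, i, digits=digits)
            )
        lines.append("")
    for prop in PROPERTY_NAMES:
        lines += [f"## Predicted vs actual: {prop}", "",
                  _md(report.predictions[prop]), ""]
    md = dest / "report.md"
    md.write_text("\n".join(lines), encoding="utf-8")
    written.append(md)
    return written
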