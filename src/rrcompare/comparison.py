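"""Comparison grids over the six mechanisms and table writers.

The default grid reproduces the published head-to-head comparison:
mu_Y = 10, var_Y = 2, n = 500; two scrambler-variance blocks
(var_S, var_T) in {(6, 8), (10, 4)}; truthful-response probabilities
p in {0.3, 0.5, 0.7}; three (A, alpha) panels {(0.8, 0.9), (0.5, 0.6),
(0.2, 0.3)}.  One cell per (panel, block, p, model) combination gives
3 * 2 * 3 * 6 = 108 cells per metric; mechanisms without p repeat their
value across the p columns, and mechanisms without A/alpha repeat across
panels, mirroring the printed layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .metrics import compute_metrics
from .models import Model, ModelParams, OPTIONAL_MODELS
from .samplers import PopulationSpec

__all__ = ["GridSpec", "build_grid", "rank_models", "write_tables", "METRICS"]

METRICS = ("variance", "privacy", "delta")

#: ranking direction per metric: privacy is better when larger
ASCENDING = {"variance": True, "privacy": False, "delta": True}

DEFAULT_BLOCKS = ((6.0, 8.0), (10.0, 4.0))
DEFAULT_P_VALUES = (0.3, 0.5, 0.7)
DEFAULT_PANELS = ((0.8, 0.9), (0.5, 0.6), (0.2, 0.3))


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for the model comparison.

    ``blocks`` are (var_S, var_T) pairs; ``panels`` are (A, alpha) pairs
    applied to the mechanisms that use them.  Defaults reproduce the
    published comparison grid.
    """

    pop: PopulationSpec = field(default_factory=lambda: PopulationSpec(mu=10.0, var=2.0))
    blocks: tuple = DEFAULT_BLOCKS
    p_values: tuple = DEFAULT_P_VALUES
    panels: tuple = DEFAULT_PANELS
    n: int = 500
    models: tuple = tuple(Model)

    def __post_init__(self) -> None:
        if not (self.blocks and self.p_values and self.panels and self.models):
            raise ValueError("blocks, p_values, panels and models must be non-empty")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _cell_params(model: Model, p: float, A: float, alpha: float) -> ModelParams:
    kwargs = {}
    if model in OPTIONAL_MODELS:
        kwargs["p"] = p
    if model is Model.GUPTA_MIXED_OPTIONAL:
        kwargs["A"] = A
    if model is Model.MURTAZA_MIXED:
        kwargs["alpha"] = alpha
    return ModelParams(model, **kwargs)


def build_grid(spec: GridSpec, privacy_mode: str = "printed") -> pd.DataFrame:
    """Evaluate the analytic metrics on every cell of the grid.

    Returns a DataFrame with one row per (panel, block, p, model) and
    columns model, panel, A, alpha, block, var_S, var_T, p, variance,
    privacy, delta.
    """
    rows = []
    for panel_idx, (A, alpha) in enumerate(spec.panels):
        for block_idx, (var_S, var_T) in enumerate(spec.blocks):
            for p in spec.p_values:
                for model in spec.models:
                    model = Model(model)
                    params = _cell_params(model, p, A, alpha)
                    m = compute_metrics(
                        params, spec.pop, var_S, var_T, spec.n, privacy_mode=privacy_mode
                    )
                    rows.append(
                        {
                            "model": model.value,
                            "panel": panel_idx,
                            "A": A,
                            "alpha": alpha,
                            "block": block_idx,
                            "var_S": var_S,
                            "var_T": var_T,
                            "p": p,
                            "variance": m.variance,
                            "privacy": m.privacy,
                            "delta": m.delta,
                        }
                    )
    return pd.DataFrame(rows)


def rank_models(
    cells: pd.DataFrame, metric: str, ascending: bool | None = None
) -> pd.DataFrame:
    """Rank the models within every (panel, block, p) parameter combination.

    Privacy ranks descending (larger nabla = better privacy) unless
    overridden; variance and delta rank ascending.  Ties are broken by the
    canonical model order and flagged in the ``tie`` column.
    """
    if cells.empty:
        raise ValueError("cells must be non-empty")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if ascending is None:
        ascending = ASCENDING[metric]
    order = {m.value: i for i, m in enumerate(Model)}
    out = cells.copy()
    out["_model_order"] = out["model"].map(order)
    group_cols = ["panel", "block", "p"]

    def _rank(group: pd.DataFrame) -> pd.DataFrame:
        g = group.sort_values(
            [metric, "_model_order"], ascending=[ascending, True], kind="mergesort"
        ).copy()
        g["rank"] = range(1, len(g) + 1)
        g["tie"] = g[metric].duplicated(keep=False)
        return g

    ranked = (
        out.groupby(group_cols, group_keys=False, sort=True)[out.columns]
        .apply(_rank)
        .drop(columns="_model_order")
        .reset_index(drop=True)
    )
    return ranked


# ---------------------------------------------------------------------------
# table writers

#: decimal places mirroring the printed tables' per-metric precision
DEFAULT_PRECISION = {"variance": 5, "privacy": 2, "delta": 6}


def _format(value: float, decimals: int | None) -> str:
    if decimals is None:
        return repr(float(value))
    # round then strip trailing zeros so 0.016000 prints as 0.016
    text = f"{round(value, decimals):.{decimals}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text or "0"


def _pivot(cells: pd.DataFrame, metric: str, decimals: int | None) -> pd.DataFrame:
    """Panel/model rows vs (block, p) columns, as in the printed layout."""
    table = cells.pivot_table(
        index=["panel", "A", "alpha", "model"],
        columns=["block", "var_S", "var_T", "p"],
        values=metric,
        sort=False,
    )
    formatted = table.map(lambda v: _format(v, decimals))
    formatted.columns = [
        f"var_S={var_s:g},var_T={var_t:g},p={p:g}"
        for _, var_s, var_t, p in formatted.columns
    ]
    return formatted.reset_index()


def _to_markdown(frame: pd.DataFrame) -> str:
    headers = [str(c) for c in frame.columns]
    body = [[str(v) for v in row] for row in frame.itertuples(index=False)]
    widths = [max(len(h), *(len(r[i]) for r in body)) for i, h in enumerate(headers)]
    lines = [
        "| " + " | ".join(h.ljust(w) for h, w in zip(headers, widths)) + " |",
        "|" + "|".join("-" * (w + 2) for w in widths) + "|",
    ]
    for row in body:
        lines.append("| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |")
    return "\n".join(lines) + "\n"


def write_tables(
    cells: pd.DataFrame,
    out_dir: str | Path,
    fmt: str = "csv",
    precision: dict | None = None,
) -> list[Path]:
    """Write one file per metric mirroring the printed panel/row/column layout.

    ``fmt`` is one of csv, tsv, markdown; ``precision`` maps metric name to
    decimal places (default mirrors the printed tables).  Returns the paths
    written.
    """
    if fmt not in ("csv", "tsv", "markdown"):
        raise ValueError(f"format must be csv, tsv or markdown, got {fmt!r}")
    precision = {**DEFAULT_PRECISION, **(precision or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = {"csv": ".csv", "tsv": ".tsv", "markdown": ".md"}[fmt]
    paths = []
    for metric in METRICS:
        frame = _pivot(cells, metric, precision.get(metric))
        path = out_dir / f"{metric}{suffix}"
        if fmt == "markdown":
            path.write_text(_to_markdown(frame))
        else:
            frame.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)
        paths.append(path)
    return paths
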