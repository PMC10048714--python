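"""Rendering of metric tables: CSVs, confusion heatmaps, text summary."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["render_report"]


def _heatmap(row: pd.Series, path: Path) -> None:
    counts = [[int(row["tp"]), int(row["fn"])], [int(row["fp"]), int(row["tn"])]]
    fig, ax = plt.subplots(figsize=(3.2, 2.8))
    ax.imshow(counts, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, counts[i][j], ha="center", va="center")
    ax.set_xticks([0, 1], ["pred diseased", "pred healthy"])
    ax.set_yticks([0, 1], ["diseased", "healthy"])
    ax.set_title(str(row["model"]), fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)


def render_report(tables: dict, out_dir) -> dict:
    """Write each metrics table as CSV (+ heatmaps) and a text summary.

    ``tables`` maps a table name to a DataFrame with at least ``model``
    and ``accuracy`` columns; rows carrying tp/tn/fp/fn also get a
    confusion-matrix heatmap PNG.  The summary names the best model per
    table by validation accuracy.  Re-rendering identical input yields
    byte-identical CSVs.
    """
    if not tables:
        raise ValueError("no tables to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_lines = []
    written = {}
    for name, df in tables.items():
        if df.empty:
            raise ValueError(f"table {name!r} is empty")
        csv_path = out / f"{name}.csv"
        df.to_csv(csv_path, index=False, lineterminator="\n")
        written[name] = csv_path
        if {"tp", "tn", "fp", "fn"}.issubset(df.columns):
            hm_dir = out / f"{name}_confusions"
            hm_dir.mkdir(exist_ok=True)
            for _, row in df.iterrows():
                _heatmap(row, hm_dir / f"{row['model']}.png")
        if "accuracy" in df.columns and "model" in df.columns:
            best = df.loc[df["accuracy"].idxmax()]
            summary_lines.append(
                f"{name}: best model {best['model']} "
                f"(validation accuracy {best['accuracy']:.3f})"
            )
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    written["summary"] = out / "summary.txt"
    return written
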