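"""Analysis surfaces: the precision-recall scatter of all model classes and
a markdown run summary.

Scatter values are copied from the ranking tables, never recomputed, so the
plot and the TSVs can never disagree.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SCATTER_COLUMNS = ["model_class", "rule", "recall", "precision", "mcc", "highlight"]


def build_scatter(*rankings: pd.DataFrame, highlight_best_combination: bool = True
                  ) -> pd.DataFrame:
    """Concatenate model rankings into one recall/precision scatter table.

    Accepts any number of ranking frames (single-cluster, count-threshold,
    combination) as produced by :mod:`polygero.rules`; rows keep their
    ``model_class`` tag. The top combination rule by MCC is flagged in the
    ``highlight`` column — the model a user would carry forward to screening.
    """
    frames = [r for r in rankings if r is not None and len(r)]
    if not frames:
        raise ValueError("no rankings supplied")
    table = pd.concat(frames, ignore_index=True)[
        ["model_class", "rule", "recall", "precision", "mcc"]].copy()
    table["highlight"] = False
    if highlight_best_combination:
        combos = table[table["model_class"] == "combination"]
        if len(combos):
            table.loc[combos["mcc"].idxmax(), "highlight"] = True
    return table[SCATTER_COLUMNS]


def plot_scatter(scatter: pd.DataFrame, path) -> None:
    """Render the scatter table (values taken verbatim from the table)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"single": "0.6", "count": "tab:green", "combination": "gold"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in scatter.groupby("model_class"):
        ax.scatter(sub["recall"], sub["precision"], s=18,
                   c=colors.get(cls, "tab:blue"), label=cls, alpha=0.8)
    best = scatter[scatter["highlight"]]
    if len(best):
        ax.scatter(best["recall"], best["precision"], s=60, c="red",
                   label="best combination", zorder=5)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize_run(run_dir) -> str:
    """Markdown report for a pipeline run directory.

    Sections: funnel ledger, top-10 rules, split statistics, config echo.
    Missing stages are marked as skipped rather than failing the report.
    """
    run_dir = Path(run_dir)
    lines = [f"# Run summary: {run_dir.name}", ""]

    lines.append("## Funnel")
    ledger_path = run_dir / "funnel_ledger.json"
    if ledger_path.exists():
        ledger = json.loads(ledger_path.read_text())
        lines += ["", "| stage | survivors |", "|---|---|"]
        lines += [f"| {k} | {v} |" for k, v in ledger.items()]
    else:
        lines.append("_screening stage skipped_")
    lines.append("")

    lines.append("## Top 10 rules")
    ranking_path = run_dir / "ranking.tsv"
    if ranking_path.exists():
        top = pd.read_csv(ranking_path, sep="\t").head(10)
        cols = ["rule", "precision", "recall", "mcc"]
        lines += ["", "| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for _, row in top.iterrows():
            lines.append("| " + " | ".join(
                f"{row[c]:.3f}" if isinstance(row[c], float) else str(row[c])
                for c in cols) + " |")
    else:
        lines.append("_rule discovery stage skipped_")
    lines.append("")

    lines.append("## Split")
    split_path = run_dir / "split.tsv"
    if split_path.exists():
        split = pd.read_csv(split_path, sep="\t")
        counts = split["partition"].value_counts()
        lines += ["", "| partition | compounds |", "|---|---|"]
        lines += [f"| {p} | {c} |" for p, c in counts.items()]
    else:
        lines.append("_training stage skipped_")
    lines.append("")

    lines.append("## Config")
    config_path = run_dir / "config.yaml"
    if config_path.exists():
        lines += ["", "```yaml", config_path.read_text().rstrip(), "```"]
    else:
        lines.append("_no config recorded_")
    lines.append("")
    return "\n".join(lines)
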