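"""Cohort summaries and static per-participant reports.

Per-participant effect estimates are assembled into forest-plot data with a
fixed-effect inverse-variance pooled row per contrast, a count matrix of
POSITIVE / NEGATIVE / NO_EFFECT labels, and a static HTML report with a
forest panel, a daily-steps line graph colored by block, and per-treatment
boxplots. The pooled row uses weights w_i = 1/SE_i^2, so its standard
error never exceeds any individual one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .design import BASELINE, MASSAGE, USUAL_CARE, YOGA
from .effects import CONTRASTS, NEGATIVE, NO_EFFECT, POSITIVE, classify_effect

POOLED = "POOLED"

_Z975 = 1.959963984540054


@dataclass
class ForestRow:
    participant_id: str  # a participant id or POOLED
    contrast: str
    beta_hat: float
    ci_low: float
    ci_high: float
    weight: float


def pool_effects(estimates: pd.DataFrame) -> ForestRow:
    """Fixed-effect inverse-variance pooling of one contrast's estimates.

    ``estimates`` holds one row per participant with ``beta_hat`` and ``se``
    columns (a single contrast). Returns the pooled forest row with a 95%
    normal-quantile CI.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate to pool")
    contrast_vals = estimates["contrast"].unique()
    if len(contrast_vals) != 1:
        raise ValueError("pool_effects expects a single contrast")
    se = estimates["se"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive for pooling")
    beta = estimates["beta_hat"].to_numpy(dtype=float)
    w = 1.0 / se**2
    pooled_beta = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    return ForestRow(
        participant_id=POOLED,
        contrast=str(contrast_vals[0]),
        beta_hat=pooled_beta,
        ci_low=pooled_beta - _Z975 * pooled_se,
        ci_high=pooled_beta + _Z975 * pooled_se,
        weight=float(np.sum(w)),
    )


def forest_frame(effects: pd.DataFrame) -> pd.DataFrame:
    """Forest-plot table: one row per (participant, contrast) plus pooled rows."""
    rows = []
    for _, r in effects.sort_values(["contrast", "participant_id"]).iterrows():
        rows.append(
            {
                "participant_id": r["participant_id"],
                "contrast": r["contrast"],
                "beta_hat": r["beta_hat"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "weight": 1.0 / float(r["se"]) ** 2,
            }
        )
    for contrast in sorted(effects["contrast"].unique()):
        pooled = pool_effects(effects[effects["contrast"] == contrast])
        rows.append(pooled.__dict__)
    return pd.DataFrame(rows)


def counts_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast counts of participants by effect label.

    Every participant must contribute all three contrasts; the three counts
    sum to the cohort size in each row.
    """
    participants = effects["participant_id"].unique()
    for pid in participants:
        have = set(effects.loc[effects["participant_id"] == pid, "contrast"])
        missing = set(CONTRASTS) - have
        if missing:
            raise ValueError(f"participant {pid!r} missing contrasts {sorted(missing)}")
    rows = []
    for contrast in CONTRASTS:
        sub = effects[effects["contrast"] == contrast]
        rows.append(
            {
                "contrast": contrast,
                "n_positive": int((sub["label"] == POSITIVE).sum()),
                "n_negative": int((sub["label"] == NEGATIVE).sum()),
                "n_no_effect": int((sub["label"] == NO_EFFECT).sum()),
            }
        )
    out = pd.DataFrame(rows)
    totals = out[["n_positive", "n_negative", "n_no_effect"]].sum(axis=1)
    assert (totals == len(participants)).all(), "label counts must sum to cohort size"
    return out


_BLOCK_COLORS = {
    BASELINE: "#9e9e9e",
    YOGA: "#1b9e77",
    MASSAGE: "#7570b3",
    USUAL_CARE: "#d95f02",
}


def _forest_plot(rows: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.35 * len(rows) + 1)))
    ys = np.arange(len(rows))[::-1]
    for y, (_, r) in zip(ys, rows.iterrows()):
        color = "#d62728" if r["participant_id"] == POOLED else "#1f77b4"
        ax.plot([r["ci_low"], r["ci_high"]], [y, y], color=color, lw=1.5)
        ax.plot(r["beta_hat"], y, "o" if r["participant_id"] != POOLED else "D", color=color)
    ax.axvline(0.0, color="black", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels(
        [f"{r['participant_id']} {r['contrast']}" for _, r in rows.iterrows()], fontsize=7
    )
    ax.set_xlabel("difference in daily steps")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _line_graph(daily: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    daily = daily.sort_values("day_index")
    ax.plot(daily["day_index"], daily["total_steps"], color="#666666", lw=0.7, zorder=1)
    for block, sub in daily.groupby("block"):
        ax.scatter(
            sub["day_index"],
            sub["total_steps"],
            s=12,
            color=_BLOCK_COLORS.get(block, "#333333"),
            label=block,
            zorder=2,
        )
    ax.set_xlabel("trial day")
    ax.set_ylabel("daily steps")
    ax.set_title(title)
    ax.legend(fontsize=7, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _boxplot(daily: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [b for b in (BASELINE, USUAL_CARE, YOGA, MASSAGE) if b in set(daily["block"])]
    data = [daily.loc[daily["block"] == b, "total_steps"].to_numpy() for b in order]
    fig, ax = plt.subplots(figsize=(5, 3))
    bp = ax.boxplot(data, tick_labels=order, patch_artist=True)
    for patch, b in zip(bp["boxes"], order):
        patch.set_facecolor(_BLOCK_COLORS.get(b, "#cccccc"))
        patch.set_alpha(0.6)
    ax.set_ylabel("daily steps")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _effects_html_table(df: pd.DataFrame) -> str:
    cols = ["contrast", "beta_hat", "se", "ci_low", "ci_high", "label"]
    head = "".join(f"<th>{c}</th>" for c in cols)
    body = ""
    for _, r in df.iterrows():
        cells = [
            r["contrast"],
            f"{r['beta_hat']:.1f}",
            f"{r['se']:.1f}",
            f"{r['ci_low']:.1f}",
            f"{r['ci_high']:.1f}",
            r["label"],
        ]
        body += "<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>\n"
    return f"<table border='1' cellpadding='4'><tr>{head}</tr>\n{body}</table>"


def render_report(
    effects: pd.DataFrame,
    daily: pd.DataFrame,
    out_dir,
    effects_unimputed: Optional[pd.DataFrame] = None,
    figures: bool = True,
) -> Path:
    """Write the static cohort + per-participant report.

    Produces ``forest.csv``, ``counts.csv`` and ``index.html`` in
    ``out_dir`` plus one page per participant with its effects table,
    forest panel, line graph and boxplot. When ``effects_unimputed`` is
    given, each participant page shows both the imputed and non-imputed
    analyses as labeled panels. Tables are byte-identical across runs on
    identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    forest = forest_frame(effects)
    counts = counts_table(effects)
    forest.to_csv(out / "forest.csv", index=False, float_format="%.6g")
    counts.to_csv(out / "counts.csv", index=False)

    if figures:
        _forest_plot(forest, out / "forest.png", "Treatment effects (all participants)")

    participant_ids = sorted(effects["participant_id"].unique())
    links = []
    for pid in participant_ids:
        page = _render_participant(
            pid, effects, daily, out, effects_unimputed=effects_unimputed, figures=figures
        )
        links.append(f"<li><a href='{page.name}'>{pid}</a></li>")

    counts_html = counts.to_html(index=False)
    index_html = f"""<html><head><title>N-of-1 step-count trial report</title></head>
<body>
<h1>Cohort summary</h1>
<p>{len(participant_ids)} participants analyzed.</p>
<h2>Effect label counts</h2>
{counts_html}
<h2>Forest plot</h2>
{"<img src='forest.png' width='700'/>" if figures else "<p>(figures disabled)</p>"}
<p>Pooled rows use fixed-effect inverse-variance weighting.</p>
<h2>Participants</h2>
<ul>
{chr(10).join(links)}
</ul>
</body></html>
"""
    (out / "index.html").write_text(index_html)
    return out / "index.html"


def _render_participant(
    pid: str,
    effects: pd.DataFrame,
    daily: pd.DataFrame,
    out: Path,
    effects_unimputed: Optional[pd.DataFrame] = None,
    figures: bool = True,
) -> Path:
    eff = effects[effects["participant_id"] == pid]
    day = daily[daily["participant_id"] == pid]
    stem = f"participant_{pid}"
    img_tags = []
    if figures:
        rows = eff.assign(weight=1.0 / eff["se"] ** 2)[
            ["participant_id", "contrast", "beta_hat", "ci_low", "ci_high", "weight"]
        ]
        _forest_plot(rows, out / f"{stem}_forest.png", f"{pid}: treatment effects")
        _line_graph(day, out / f"{stem}_line.png", f"{pid}: daily steps by block")
        _boxplot(day, out / f"{stem}_box.png", f"{pid}: daily steps per condition")
        img_tags = [
            f"<img src='{stem}_forest.png' width='640'/>",
            f"<img src='{stem}_line.png' width='720'/>",
            f"<img src='{stem}_box.png' width='480'/>",
        ]
    sections = [
        "<h2>Effects (imputed daily totals)</h2>",
        _effects_html_table(eff),
    ]
    if effects_unimputed is not None:
        eff0 = effects_unimputed[effects_unimputed["participant_id"] == pid]
        sections += [
            "<h2>Effects (non-imputed daily totals)</h2>",
            _effects_html_table(eff0),
        ]
    html = f"""<html><head><title>{pid}</title></head>
<body>
<h1>Participant {pid}</h1>
{chr(10).join(sections)}
{chr(10).join(img_tags)}
<p><a href='index.html'>back to cohort</a></p>
</body></html>
"""
    page = out / f"{stem}.html"
    page.write_text(html)
    return page
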