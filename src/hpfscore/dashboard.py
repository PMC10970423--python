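"""Whole-of-framework dashboard rendering.

One panel per (jurisdiction, tier), one bar per group: green bars for mean
improvement, red for mean worsening, grey for exactly zero, with error bars
spanning the displayed 95% interval (mean ± 1.96·SEM) where the SEM is
defined.  The y axis is fixed to [−3, 3] on every panel so bar heights are
comparable across the whole figure; error bars that would leave that range
are clipped and marked with a small caret.

Output is deterministic for fixed input: rendering the same summaries twice
produces byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg", force=False)  # never require a display

import matplotlib.pyplot as plt

from .framework import UNDEFINED, FrameworkSpec, GroupSummary

__all__ = ["DashboardConfig", "render"]

Y_RANGE = (-3.0, 3.0)


@dataclass(frozen=True)
class DashboardConfig:
    """Colours, format and sizing for the dashboard grid."""

    colour_positive: str = "#2e7d32"  # green: average improvement
    colour_negative: str = "#c62828"  # red: average worsening
    colour_zero: str = "#9e9e9e"      # grey: exactly no average change
    output_format: str = "svg"        # svg | png | html
    panel_width: float = 3.2
    panel_height: float = 2.2

    def __post_init__(self) -> None:
        if self.output_format not in ("svg", "png", "html"):
            raise ValueError(
                f"output_format must be svg, png or html, got {self.output_format!r}"
            )


def _bar_colour(mean: float, config: DashboardConfig) -> str:
    if mean > 0:
        return config.colour_positive
    if mean < 0:
        return config.colour_negative
    return config.colour_zero


def render(
    summaries: Sequence[GroupSummary],
    config: DashboardConfig = DashboardConfig(),
    out_path: Union[str, Path] = "dashboard.svg",
    framework: Optional[FrameworkSpec] = None,
) -> Path:
    """Render group summaries to a jurisdiction × tier grid of bar panels.

    *out_path* may be a file path or a directory (a ``dashboard.<format>``
    file is created inside).  When a *framework* is given, bars within each
    panel follow its group declaration order for cross-panel comparability;
    otherwise order of first appearance is used.  Returns the written path.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to render")

    out_path = Path(out_path)
    if out_path.is_dir():
        out_path = out_path / f"dashboard.{config.output_format}"

    jurisdictions = list(dict.fromkeys(s.jurisdiction for s in summaries))
    tiers = sorted({s.tier_number for s in summaries})

    if framework is not None:
        order = {
            (t.number, g.name): i
            for i, (t, g) in enumerate((t, g) for t in framework.tiers for g in t.groups)
        }
    else:
        order = {
            (s.tier_number, s.group_name): i for i, s in enumerate(summaries)
        }

    with plt.rc_context({"svg.hashsalt": "hpfscore", "figure.dpi": 100}):
        fig, axes = plt.subplots(
            len(jurisdictions),
            len(tiers),
            figsize=(
                config.panel_width * len(tiers),
                config.panel_height * len(jurisdictions),
            ),
            squeeze=False,
            sharey=True,
        )
        for i, juris in enumerate(jurisdictions):
            for j, tier in enumerate(tiers):
                ax = axes[i][j]
                panel = sorted(
                    (
                        s
                        for s in summaries
                        if s.jurisdiction == juris and s.tier_number == tier
                    ),
                    key=lambda s: order.get((s.tier_number, s.group_name), -1),
                )
                _draw_panel(ax, panel, config)
                if i == 0:
                    ax.set_title(f"Tier {tier}", fontsize=9)
                if j == 0:
                    ax.set_ylabel(juris, fontsize=9)
        fig.tight_layout()
        _save(fig, out_path, config)
        plt.close(fig)
    return out_path


def _draw_panel(
    ax: plt.Axes, panel: Sequence[GroupSummary], config: DashboardConfig
) -> None:
    ax.set_ylim(*Y_RANGE)
    ax.axhline(0.0, color="#555555", linewidth=0.6)
    ax.set_xticks([])
    ax.tick_params(labelsize=7)
    if not panel:
        return
    xs = range(len(panel))
    heights = [s.mean_score for s in panel]
    colours = [_bar_colour(h, config) for h in heights]
    ax.bar(xs, heights, color=colours, width=0.7)
    for x, s in zip(xs, panel):
        if s.sem is UNDEFINED:
            continue  # n = 1: nothing to draw
        lo, hi = s.ci_low, s.ci_high
        clip_lo, clip_hi = max(lo, Y_RANGE[0]), min(hi, Y_RANGE[1])
        ax.vlines(x, clip_lo, clip_hi, color="#222222", linewidth=0.9)
        # carets mark interval ends clipped by the fixed [-3, 3] axis
        if lo < Y_RANGE[0]:
            ax.plot(x, Y_RANGE[0], marker="v", color="#222222", markersize=3)
        if hi > Y_RANGE[1]:
            ax.plot(x, Y_RANGE[1], marker="^", color="#222222", markersize=3)
    ax.set_xticks(list(xs))
    ax.set_xticklabels(
        [_shorten(s.group_name) for s in panel], rotation=45, ha="right", fontsize=6
    )


def _shorten(name: Optional[str], limit: int = 18) -> str:
    if not name:
        return ""
    return name if len(name) <= limit else name[: limit - 1] + "…"


def _save(fig: plt.Figure, out_path: Path, config: DashboardConfig) -> None:
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if config.output_format == "png":
        fig.savefig(out_path, format="png")
        return
    # SVG with a pinned hashsalt and no timestamp is byte-reproducible
    import io

    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    svg = buf.getvalue()
    if config.output_format == "svg":
        out_path.write_text(svg, encoding="utf-8")
    else:  # html: the same SVG in a minimal static page
        out_path.write_text(
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>Improvement dashboard</title></head>\n<body>\n"
            + svg
            + "\n</body></html>\n",
            encoding="utf-8",
        )
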