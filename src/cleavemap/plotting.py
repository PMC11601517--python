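"""Minimal matplotlib rendering of logos and anchored profiles.

Letter heights are drawn as stacked colored bars per dyad-relative position
(conventional base colors: A green, C blue, G orange, T red). These plots
are diagnostic output, not publication-grade glyph logos.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from cleavemap.composition import AverageProfile, LogoMatrix
from cleavemap.synth import BASES

BASE_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def plot_logo(logo: LogoMatrix, path: str) -> None:
    """Stacked-bar information logo; per-base stacking ordered by height."""
    positions = np.array(logo.relative_positions)
    x = np.arange(len(positions))
    fig, ax = plt.subplots(figsize=(max(4, len(positions) * 0.4), 3))
    for i in range(len(positions)):
        order = np.argsort(logo.heights[i])
        bottom = 0.0
        for j in order:
            h = logo.heights[i, j]
            if h <= 0:
                continue
            ax.bar(x[i], h, bottom=bottom, color=BASE_COLORS[BASES[j]], width=0.8)
            bottom += h
    ax.set_xticks(x)
    ax.set_xticklabels([f"{p:+d}" for p in positions], fontsize=7)
    ax.set_xlabel("position relative to dyad axis")
    ax.set_ylabel("information (bits)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=BASE_COLORS[b]) for b in BASES]
    ax.legend(handles, list(BASES), ncol=4, fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile(profile: AverageProfile, path: str) -> None:
    """Mean strand-specific signal around the anchors."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.offsets, profile.top, color="#255C99", label="top")
    ax.plot(profile.offsets, profile.bottom, color="#D62839", label="bottom")
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("mean signal")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
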