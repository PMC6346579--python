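"""Bullseye effect-size plots.

Nine angular sectors (FL, FR, PL, PR, OL, OR, TL, TR, BG) by four
concentric rings (ring 1 innermost = periventricular).  Cells are colored
by effect size only where the FDR-adjusted permutation p is below 0.05;
non-significant cells render neutral grey.  The diverging colormap is
symmetric about zero (hot = positive association, cold = negative).
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .parcellation import region_code  # noqa: E402

#: angular sector order of the bullseye, clockwise from the top
SECTOR_ORDER = ("FL", "FR", "PL", "PR", "OL", "OR", "TL", "TR", "BG")


def plot_bullseye(results: pd.DataFrame, path, title: str | None = None,
                  vmax: float | None = None, alpha: float = 0.05) -> list[str]:
    """Render one predictor x model result set as a bullseye figure.

    ``results`` must contain the 36 regional rows (columns: region, effect,
    q_fdr, effect_kind) of a single contrast.  ``path`` is the output base
    name or a .png/.svg file name; both a PNG and an SVG are written.
    Returns the written file names.
    """
    reg = results[results["region"] != "global"]
    if reg["contrast"].nunique() > 1:
        raise ValueError("plot_bullseye expects the results of one contrast")
    present = set(int(r) for r in reg["region"])
    missing = set(range(1, 37)) - present
    if missing:
        raise ValueError(f"missing region codes: {sorted(missing)}")

    effect = np.zeros((9, 4))
    sig = np.zeros((9, 4), dtype=bool)
    by_code = {int(r.region): r for r in reg.itertuples()}
    for s, seg in enumerate(SECTOR_ORDER):
        for layer in (1, 2, 3, 4):
            r = by_code[region_code(seg, layer)]
            effect[s, layer - 1] = r.effect if np.isfinite(r.effect) else 0.0
            sig[s, layer - 1] = bool(r.q_fdr < alpha) if np.isfinite(r.q_fdr) \
                else False

    if vmax is None:
        vmax = float(np.abs(effect[sig]).max()) if sig.any() else 1.0
        vmax = max(vmax, 1e-6)
    masked = np.ma.masked_where(~sig, effect)

    theta_edges = np.linspace(0, 2 * np.pi, 10)
    r_edges = np.arange(1, 6)  # ring 1 innermost, hole of radius 1 in the middle
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad("0.88")

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    mesh = ax.pcolormesh(theta_edges, r_edges, masked.T, cmap=cmap,
                         vmin=-vmax, vmax=vmax, shading="flat")
    ax.set_yticks([])
    ax.set_xticks((theta_edges[:-1] + theta_edges[1:]) / 2)
    ax.set_xticklabels(SECTOR_ORDER)
    ax.set_ylim(0, 5)
    ax.grid(False)
    ax.spines["polar"].set_visible(False)
    kind = reg["effect_kind"].dropna().unique()
    kind_label = {"spearman_rho": "Spearman $\\rho$",
                  "cohens_d": "Cohen's $d$"}.get(kind[0] if len(kind) else "",
                                                 "effect size")
    fig.colorbar(mesh, ax=ax, shrink=0.7, label=kind_label)
    if title:
        ax.set_title(title, pad=18)

    base = str(path)
    for ext in (".png", ".svg"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    written = []
    for ext in (".png", ".svg"):
        fig.savefig(base + ext, bbox_inches="tight", dpi=150)
        written.append(base + ext)
    plt.close(fig)
    return written
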