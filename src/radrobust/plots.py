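"""Stability-vs-internal-quality scatter plots for the grid report."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from radrobust.stability import StabilityRecord  # noqa: E402

__all__ = ["stability_scatter"]

_MARKERS = {"ward.D2": "o", "average": "s", "complete": "^",
            "single": "v", "centroid": "D"}


def stability_scatter(
    records: list[StabilityRecord], side: str, path: str
) -> None:
    """ARI (y) vs silhouette (x), Dunn index as color, linkage as marker shape.

    ``side`` selects which platform's internal indices to plot ("a" or "b").
    """
    if side not in {"a", "b"}:
        raise ValueError("side must be 'a' or 'b'")
    fig, ax = plt.subplots(figsize=(7, 5))
    sc = None
    for linkage, marker in _MARKERS.items():
        rows = [r for r in records if r.linkage == linkage and r.error is None]
        if not rows:
            continue
        xs = [getattr(r, f"silhouette_{side}") for r in rows]
        ys = [r.ari for r in rows]
        cs = [getattr(r, f"dunn_{side}") for r in rows]
        sc = ax.scatter(xs, ys, c=cs, marker=marker, label=linkage,
                        cmap="viridis", vmin=0, edgecolors="k", linewidths=0.4)
    if sc is not None:
        fig.colorbar(sc, ax=ax, label="Dunn index")
    ax.set_xlabel("Silhouette score")
    ax.set_ylabel("Adjusted Rand Index")
    ax.set_title(f"Clustering stability vs internal quality (platform {side.upper()})")
    ax.legend(title="linkage", fontsize=8)
    ax.axhline(0.8, color="grey", ls="--", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
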