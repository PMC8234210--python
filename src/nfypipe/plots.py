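"""Minimal matplotlib figures: Kaplan–Meier step curves and per-bin subtype
composition bars.  Figures are written to file; no interactive backend is
assumed."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from nfypipe.survival import SurvivalCurve  # noqa: E402


def plot_km_curves(curves: dict[str, SurvivalCurve], path,
                   title: str = "Progression-free interval") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in sorted(curves.items()):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival_prob])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bin_composition(composition, path,
                         title: str = "Subtype composition by ratio bin") -> None:
    """Stacked bars of subtype fractions per rank bin (rows = bins)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(composition))
    for subtype in composition.columns:
        ax.bar(composition.index.astype(str), composition[subtype],
               bottom=bottom, label=subtype)
        bottom += composition[subtype].to_numpy()
    ax.set_xlabel("ratio bin (increasing NF-YAl/NF-YAs)")
    ax.set_ylabel("fraction of samples")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
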