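"""Optional plotting helpers (requires matplotlib, installed separately)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .stats import AgreementPair, bland_altman


def bland_altman_plot(pairs: list[AgreementPair], path: str | Path) -> Path:
    """Save a Bland-Altman plot (difference vs mean with limits of agreement)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    a = np.array([p.measurement_a for p in pairs])
    b = np.array([p.measurement_b for p in pairs])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.6)
    ax.axhline(res.mean_diff, color="k", lw=1, label=f"mean {res.mean_diff:.2f}")
    for y in (res.loa_lower, res.loa_upper):
        ax.axhline(y, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of methods (mm$^2$)")
    ax.set_ylabel("difference (mm$^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
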