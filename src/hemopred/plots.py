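"""Basic scatter and Bland-Altman figures for prediction sets."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .evaluation import bland_altman  # noqa: E402

__all__ = ["scatter_and_bland_altman"]


def scatter_and_bland_altman(pred, ref, path: str | Path,
                             label: str = "", units: str = "") -> Path:
    """Side-by-side identity scatter and Bland-Altman plot; returns path."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ba = bland_altman(pred, ref)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(ref, pred, s=6, alpha=0.5)
    lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
    ax1.plot(lims, lims, "k-", lw=1)
    ax1.set_xlabel(f"reference {label} {units}".strip())
    ax1.set_ylabel(f"predicted {label} {units}".strip())
    mean = 0.5 * (pred + ref)
    ax2.scatter(mean, pred - ref, s=6, alpha=0.5)
    ax2.axhline(ba.bias, color="k", lw=1)
    for loa in (ba.loa_low, ba.loa_high):
        ax2.axhline(loa, color="k", lw=1, ls="--")
    ax2.set_xlabel(f"mean {label} {units}".strip())
    ax2.set_ylabel(f"difference {units}".strip())
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
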