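"""Growth-curve plots: fitted mean, ±2 SD band, and bootstrap CI band."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .reference import ReferenceCurve, ReferenceSet

__all__ = ["plot_reference_curve", "plot_reference_set"]


def plot_reference_curve(curve: ReferenceCurve, path: Union[str, Path],
                         points: Optional[np.ndarray] = None) -> None:
    """Render one reference curve to an image file.

    Shows the fitted mean over the sampled age range, the ±2 SD envelope
    (bounding ~95% of individuals), and the 95% CI of the mean when a
    bootstrap band was computed; optionally overlays the (age, value)
    scatter the curve was fitted to.
    """
    ages = curve.sd_profile.ages
    mean = np.asarray(curve.mean_at(ages))
    sd = curve.sd_profile.sd

    fig, ax = plt.subplots(figsize=(7, 4.5))
    if points is not None:
        pts = np.asarray(points, float)
        ax.plot(pts[:, 0], pts[:, 1], ".", ms=3, alpha=0.4, color="grey", label="subjects")
    ax.fill_between(ages, mean - 2 * sd, mean + 2 * sd, alpha=0.18,
                    color="tab:blue", label="±2 SD")
    if curve.ci is not None:
        ax.fill_between(curve.ci.ages, curve.ci.lower, curve.ci.upper, alpha=0.35,
                        color="tab:orange", label=f"{int(curve.ci.level * 100)}% CI of mean")
    ax.plot(ages, mean, color="tab:blue", lw=2,
            label=f"mean ({curve.model.family})")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{curve.measurement} (mm)")
    ax.set_title(f"{curve.measurement} — sex {curve.sex} "
                 f"(n={curve.n_subjects}, outliers removed={curve.outliers_removed})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reference_set(refset: ReferenceSet, out_dir: Union[str, Path]) -> list[Path]:
    """Render every curve of a reference set into *out_dir*; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for curve in refset.curves:
        p = out / f"{curve.measurement}_{curve.sex}.png"
        plot_reference_curve(curve, p)
        paths.append(p)
    return paths
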