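"""Plotting helpers: the timing figure and Bland-Altman panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .timing import PhaseEstimate, difference_curve

__all__ = ["plot_timing", "plot_bland_altman"]


def plot_timing(aif, vof, fov_mean, cta_arterial, cta_venous, estimate: PhaseEstimate, out):
    """Timing-analysis figure: AIF/VOF/FOV curves, the AIF−VOF difference,
    the constant CTA levels, and the estimated acquisition time."""
    diff = difference_curve(aif, vof)
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(aif.times, aif.values, label="AIF (CTP)", color="tab:red")
    ax.plot(vof.times, vof.values, label="VOF (CTP)", color="tab:blue")
    if fov_mean is not None:
        ax.plot(fov_mean.times, fov_mean.values, label="FOV mean", color="tab:orange")
    ax.plot(diff.times, diff.values, label="AIF − VOF", color="tab:green")
    ax.axhline(cta_arterial, ls=":", color="tab:red", label="CTA arterial")
    ax.axhline(cta_venous, ls=":", color="tab:blue", label="CTA venous")
    ax.axhline(cta_arterial - cta_venous, ls=":", color="tab:green", label="CTA difference")
    ax.axvline(estimate.t_est, color="k", lw=1)
    ax.annotate(
        f"t_est = {estimate.t_est:.1f} s\n{estimate.phase}",
        (estimate.t_est, ax.get_ylim()[1] * 0.9),
        fontsize=9,
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("attenuation (HU)")
    ax.legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def plot_bland_altman(estimate, reference, out, label="reference"):
    """Bland-Altman scatter with mean-difference and percentile-limit lines."""
    estimate = np.asarray(estimate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    d = estimate - reference
    mean_pair = (estimate + reference) / 2.0
    lo, hi = np.percentile(d, [2.5, 97.5])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(mean_pair, d, s=14, alpha=0.6)
    ax.axhline(d.mean(), color="k")
    ax.axhline(lo, color="k", ls=":")
    ax.axhline(hi, color="k", ls=":")
    ax.set_xlabel(f"mean of estimate and {label} (mL)")
    ax.set_ylabel(f"estimate − {label} (mL)")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
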