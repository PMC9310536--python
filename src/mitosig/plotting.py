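"""Optional plots: per-stack depth profiles of the clustering exponent."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from mitosig.profiles import DepthProfile

__all__ = ["plot_profile", "plot_profiles"]


def plot_profile(profile: DepthProfile, path: str | Path, title: str | None = None):
    """One profile: per-slice beta (points) with the smoothing spline."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ok = profile.ok_mask
    ax.plot(profile.depth_um[ok], profile.betas[ok], "o", ms=4, label="per-slice")
    if profile.complete:
        ax.plot(profile.smooth_depth, profile.smooth_beta, "-", label="spline")
    ax.set_xlabel("depth (µm)")
    ax.set_ylabel(r"clustering exponent $\beta$")
    ax.set_title(title or profile.stack_meta.get("stack_id", ""))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_profiles(
    profiles: Sequence[DepthProfile], outdir: str | Path, fmt: str = "png"
) -> list[Path]:
    """One file per profile, named by stack id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = []
    for p in profiles:
        sid = p.stack_meta.get("stack_id", f"stack{len(out)}")
        out.append(plot_profile(p, outdir / f"{sid}.{fmt}"))
    return out
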