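"""Figure export: residue × time deviation heat maps and deviation profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_twist_map(tmap, integ, path: str | Path) -> None:
    """Two-panel figure: Δθ(residue, time) heat map and the per-residue
    time-integrated deviation bar chart."""
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.2), width_ratios=[2, 1], constrained_layout=True
    )
    extent = [
        tmap.frame_times[0] * 1e-6,
        tmap.frame_times[-1] * 1e-6,
        tmap.residue_ids[-1] + 0.5,
        tmap.residue_ids[0] - 0.5,
    ]
    vmax = max(1.0, abs(tmap.delta_theta).max())
    im = ax1.imshow(
        tmap.delta_theta, aspect="auto", cmap="RdBu_r",
        vmin=-vmax, vmax=vmax, extent=extent,
    )
    ax1.set_xlabel("time (μs)")
    ax1.set_ylabel("residue")
    fig.colorbar(im, ax=ax1, label="Δθ (°)")

    ax2.barh(integ.residue_ids, integ.value, color="0.3")
    ax2.set_xlabel("∫|Δθ| dt (°·μs)")
    ax2.set_ylabel("residue")
    ax2.invert_yaxis()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
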