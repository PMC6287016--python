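"""Trial plots: posterior heatmaps, free-energy traces, agency trace."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trial"]


def plot_trial(log, out_dir) -> list:
    """Render heatmap + line plots for one trial; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    seq = np.asarray(log.sequence_posterior).T   # (hypotheses, steps)
    sch = np.asarray(log.schema_posterior).T
    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for ax, mat, title in ((axes[0], sch, "schema level"), (axes[1], seq, "sequence level")):
        im = ax.imshow(
            mat, aspect="auto", origin="lower", cmap="Greens_r", vmin=0.0, vmax=0.6,
            interpolation="nearest",
        )
        ax.set_ylabel("hypothesis")
        ax.set_title(f"posterior over time — {title}")
        fig.colorbar(im, ax=ax, label="P")
    axes[1].set_xlabel("step")
    path = out_dir / "posteriors.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(9, 4))
    steps = np.arange(log.n_steps)
    ax.plot(steps, log.free_energy_vision, label="vision", lw=0.8)
    ax.plot(steps, log.free_energy_sequence, label="sequence", lw=1.2)
    ax.plot(steps, log.free_energy_schema, label="schema", lw=1.2)
    ax.set_xlabel("step")
    ax.set_ylabel("free energy (nats)")
    ax.set_title(f"free energy — scenario {log.scenario}")
    ax.legend()
    path = out_dir / "free_energy.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    if len(log.agency):
        fig, ax = plt.subplots(figsize=(9, 3.5))
        ax.plot(np.arange(len(log.agency)), log.agency.values, marker="o", ms=3)
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("sequence-level evidence step")
        ax.set_ylabel("sense of agency")
        ax.set_title(f"agency estimate — scenario {log.scenario}")
        path = out_dir / "agency.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
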