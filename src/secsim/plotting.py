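"""Diagnostic figures for scenario results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_rud_vs_demand", "plot_rud_vs_telematics", "plot_speed_profile"]


def plot_rud_vs_demand(results: pd.DataFrame, path) -> Path:
    """Mean RUD against traffic demand, one line per camera layout."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for sec, g in results.groupby("sec_type"):
        m = g.groupby("demand_vph")["rud_pct"].mean()
        ax.plot(m.index, m.to_numpy(), marker="o", label=sec)
    ax.set_xlabel("demand (VPH)")
    ax.set_ylabel("RUD (%)")
    ax.legend(title="layout")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_rud_vs_telematics(results: pd.DataFrame, path) -> Path:
    """Mean RUD against telematics penetration, one line per camera layout."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for sec, g in results.groupby("sec_type"):
        m = g.groupby("telematics_pct")["rud_pct"].mean()
        ax.plot(m.index, m.to_numpy(), marker="o", label=sec)
    ax.set_xlabel("telematics installation (%)")
    ax.set_ylabel("RUD (%)")
    ax.legend(title="layout")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_speed_profile(profiles: dict[str, pd.DataFrame], path, cameras=()) -> Path:
    """Position-binned mean speed per driver group; camera positions marked."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, prof in profiles.items():
        ax.plot(prof["bin_center"], prof["mean_speed_kmh"], label=label)
    for c in cameras:
        ax.axvline(c, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("position (m)")
    ax.set_ylabel("mean speed (km/h)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
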