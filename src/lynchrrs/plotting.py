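"""Cosmetic plotting helpers: cumulative incidence and survival curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .risk import CumulativeIncidenceCurve
from .survival import SurvivalCurve


def plot_cumulative_incidence(curves: list[CumulativeIncidenceCurve], path: str) -> None:
    """Q(age) by gene, one panel per endpoint present."""
    endpoints = sorted({c.endpoint for c in curves})
    fig, axes = plt.subplots(1, len(endpoints), figsize=(5 * len(endpoints), 4), squeeze=False)
    for ax, ep in zip(axes[0], endpoints):
        for c in (c for c in curves if c.endpoint == ep):
            ages = sorted(c.q)
            ax.plot(ages, [c.q[a] for a in ages], label=c.gene)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("cumulative incidence")
        ax.set_title(ep)
        ax.legend()
        ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_survival(curves: list[SurvivalCurve], path: str) -> None:
    """Kaplan-Meier step curves since diagnosis."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.step(c.times, c.survival, where="post", label=f"{c.endpoint} (n={c.n_cases})")
    ax.set_xlabel("years since diagnosis")
    ax.set_ylabel("crude survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
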