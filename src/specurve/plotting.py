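"""Specification-curve figure: effect curve with evidence colors, the
settings matrix, and the permutation-null percentile band."""

from __future__ import annotations

import numpy as np

from .multiverse import SpecificationCurve

__all__ = ["plot_specification_curve"]

_DECISIONS = [
    ("epoch_length", lambda s: f"{s.epoch_length:g} s"),
    ("taper", lambda s: s.taper),
    ("avg_psd", lambda s: "yes" if s.avg_psd else "no"),
    ("fit_range", lambda s: f"{s.fit_range[0]:g}-{s.fit_range[1]:g} Hz"),
    ("knee", lambda s: "yes" if s.knee else "no"),
]


def plot_specification_curve(
    curve: SpecificationCurve,
    null_effects: np.ndarray | None = None,
    ax=None,
):
    """Three-panel layout: sorted effects (color = log10 BF10), the analytic
    settings of each specification, and (optionally) the 2.5/50/97.5
    percentile band of sorted null curves (B x K array of effects)."""
    import matplotlib.pyplot as plt

    n_panels = 3 if null_effects is not None else 2
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10, 2.5 * n_panels), sharex=True,
        gridspec_kw={"height_ratios": [2, 2] + ([2] if n_panels == 3 else [])},
    )
    effects = curve.effects
    x = np.arange(effects.size)
    log_bf = np.log10([r.bayes.bf10 for r in curve.results])
    sc = axes[0].scatter(x, effects, c=np.clip(log_bf, -1, 1), cmap="coolwarm", vmin=-1, vmax=1)
    axes[0].axhline(0.0, color="grey", lw=0.5)
    axes[0].set_ylabel("Cohen's d" if curve.analysis == "group" else "Pearson r")
    fig.colorbar(sc, ax=axes[0], label="log10 BF10")

    labels, ypos = [], []
    y = 0
    for name, getter in _DECISIONS:
        options = sorted({getter(r.specification) for r in curve.results})
        for opt in options:
            xs = [i for i, r in enumerate(curve.results) if getter(r.specification) == opt]
            axes[1].scatter(xs, [y] * len(xs), marker="|", s=60, color="k")
            labels.append(f"{name}: {opt}")
            ypos.append(y)
            y += 1
    axes[1].set_yticks(ypos, labels, fontsize=7)
    axes[1].invert_yaxis()

    if null_effects is not None:
        sorted_null = np.sort(np.asarray(null_effects), axis=1)
        for q, style in ((2.5, "--"), (50, "-"), (97.5, "--")):
            axes[2].plot(x, np.percentile(sorted_null, q, axis=0), style, color="grey", lw=1)
        axes[2].plot(x, effects, color="purple", lw=1.5)
        axes[2].set_ylabel("effect")
    axes[-1].set_xlabel("specification (sorted by effect size)")
    fig.tight_layout()
    return fig
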