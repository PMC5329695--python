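"""Optional stacked-bar rendering of composition profiles.

Matplotlib is imported lazily; the rest of the package never needs it.
Colour encoding: blue A, red T, green G, purple C, black gap.
"""

from __future__ import annotations

from .coverage import CompositionProfile

COLORS = {"A": "tab:blue", "T": "tab:red", "G": "tab:green",
          "C": "tab:purple", "gap": "black"}


def plot_composition(profile: CompositionProfile, path: str,
                     title: str | None = None) -> None:
    """Write a stacked per-position base-frequency bar chart to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freqs = profile.frequencies(include_gap=True)
    fig, ax = plt.subplots(figsize=(max(6, len(freqs) * 0.25), 3.5))
    bottom = None
    for base in ("A", "T", "G", "C", "gap"):
        ax.bar(freqs.index, freqs[base], bottom=bottom,
               color=COLORS[base], width=0.85, label=base)
        bottom = freqs[base] if bottom is None else bottom + freqs[base]
    ax.set_xlabel("E. coli position")
    ax.set_ylabel("frequency")
    ax.set_ylim(0, 1)
    ax.legend(ncol=5, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
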