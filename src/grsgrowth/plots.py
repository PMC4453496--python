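"""Optional figure analogues: score distribution and effect-by-age curve."""

from __future__ import annotations


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_score_distribution(score_summary, path=None):
    """Histogram of the allele score with unadjusted mean +/- SE outcome per bin."""
    plt = _mpl()
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    ax1.bar(score_summary["score_bin"], score_summary["n"], color="0.6")
    ax1.set_ylabel("individuals")
    ax2.errorbar(score_summary["score_bin"], score_summary["mean_z"],
                 yerr=score_summary["se_z"], fmt="o", color="k", capsize=2)
    ax2.axhline(0.0, lw=0.5, color="0.5")
    ax2.set_xlabel("combined risk-allele score")
    ax2.set_ylabel("mean zWT-HT (+/- SE)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_effect_by_age(curve, path=None):
    """Predicted per-allele effect on zWT-HT as a function of age with 95% CI."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["age"], curve["effect"], "k-", lw=2)
    ax.plot(curve["age"], curve["ci_low"], "k-", lw=0.8)
    ax.plot(curve["age"], curve["ci_high"], "k-", lw=0.8)
    ax.axhline(0.0, lw=0.5, color="0.5")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("zWT-HT per allele")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
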