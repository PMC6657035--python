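"""Diagnostic figures: misclassification-vs-iteration and correlation scatter."""

from __future__ import annotations

from .selection import SelectionTrace


def plot_selection_trace(trace: SelectionTrace, path=None):
    """OOB misclassification (overall and per class) across RF iterations."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = trace.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame.index, frame["oob_case"], "o-", label="case (asthma)")
    ax.plot(frame.index, frame["oob_control"], "s-", label="control")
    ax.plot(frame.index, frame["oob_misclassification"], "^--", label="overall", alpha=0.6)
    if trace.selected_iteration is not None:
        ax.axvline(trace.selected_iteration, color="grey", ls=":", label="selected")
    ax.set_xlabel("iteration")
    ax.set_ylabel("OOB misclassification")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation(x, y, xlabel: str, ylabel: str, path=None):
    """Scatter plot for a reported correlation (e.g. M-values vs expression)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
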