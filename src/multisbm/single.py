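"""Single-network baseline: the individual-network SBM fitted by VB.

This is the T=1 special case of the multi-network model with the
instantaneous assignment structurally tied to the root (``Q == Q^(1)``), so
the transition machinery drops out and the algorithm reduces to the
classical single-network variational SBM.  The baseline shares the
multi-network code path (same expectations, normalization and Beta/Dirichlet
updates), so comparisons against it isolate the effect of the multi-network
coupling alone.
"""

from __future__ import annotations

from .datatypes import Hyperparameters, MultiNetwork, VariationalState
from .vb import FitOptions, fit

__all__ = ["fit_single"]


def fit_single(
    net: MultiNetwork, hyper: Hyperparameters, opts: FitOptions | None = None
) -> VariationalState:
    """Fit the single-network SBM baseline on a one-network input.

    The returned state has ``Q`` identical to ``Q_t[0]`` and a free-energy
    trace for the single-network model (no transition terms, one assignment
    entropy).
    """
    if net.n_networks != 1:
        raise ValueError(
            f"fit_single requires exactly one network, got {net.n_networks}"
        )
    return fit(net, hyper, opts, tie_single=True)
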