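"""Optional matplotlib convenience wrappers (no acceptance weight)."""

from __future__ import annotations

from .simulate import Trajectory

__all__ = ["plot_time_series", "plot_phase_portrait"]


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib; install seirvax[plot]") from exc
    return plt


def plot_time_series(traj: Trajectory, ax=None, components=("s", "e", "i")):
    """Plot selected proportion components against time."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    for name in components:
        ax.plot(traj.times, getattr(traj, name), label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("proportion")
    ax.legend()
    return ax


def plot_phase_portrait(traj: Trajectory, ax=None, x: str = "s", y: str = "i"):
    """Plot one proportion component against another along the trajectory."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(getattr(traj, x), getattr(traj, y), lw=0.8)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax
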