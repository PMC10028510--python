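"""Study plots: inputs on top, difficulty response below.

Requires matplotlib (optional extra ``plot``); imported lazily so the core
loop has no plotting dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .scenarios import Scenario
from .study import StudyResult


def plot_study(
    scn: Scenario,
    results: Mapping[str, StudyResult],
    out_path: str | Path | None = None,
):
    """Two-panel figure: scenario inputs (score, mean HR) and per-game
    end-of-session difficulty for each mode.  Returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    games = range(1, scn.n_games + 1)
    has_hr = scn.hr_scripts is not None
    n_rows = 3 if has_hr else 2
    fig, axes = plt.subplots(n_rows, 1, figsize=(8, 2.4 * n_rows), sharex=True)

    axes[0].plot(games, scn.score_series, "o-", ms=3, color="tab:blue")
    axes[0].set_ylabel("score")
    row = 1
    if has_hr:
        means = [sum(s) / len(s) for s in scn.hr_scripts]
        axes[1].plot(games, means, "o-", ms=3, color="tab:red")
        axes[1].axhline(scn.hr_max, ls="--", color="k", lw=0.8)
        axes[1].set_ylabel("mean HR (bpm)")
        row = 2
    for mode, result in results.items():
        axes[row].plot(games, result.difficulty_by_game, "o-", ms=3, label=mode)
    axes[row].set_ylabel("end difficulty")
    axes[row].set_xlabel("game")
    axes[row].legend()
    fig.suptitle(scn.name)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
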