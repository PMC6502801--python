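"""Canonical 2x2 games and a reproducible random-game generator.

The three canonical payoff structures cover the qualitatively distinct
dynamical regimes of a 2x2 game:

* dominance ``(1,1,0,0)`` — A is favored at every mixed state;
* coexistence ``(0,1,1,0)`` — the interior mixed equilibrium attracts,
  fixation takes long under selection;
* bistability ``(1,0,0,1)`` — both monomorphic states are locally stable,
  invasion is hard and boundary-to-boundary transitions are rare.
"""

from __future__ import annotations

import numpy as np

from .core import Game

__all__ = ["canonical_games", "random_game"]


def canonical_games() -> dict[str, Game]:
    """The three labelled canonical games used throughout validation."""
    return {
        "dominance": Game(1.0, 1.0, 0.0, 0.0),
        "coexistence": Game(0.0, 1.0, 1.0, 0.0),
        "bistability": Game(1.0, 0.0, 0.0, 1.0),
    }


def random_game(
    rng: np.random.Generator, low: float = -1.0, high: float = 1.0
) -> Game:
    """A game with i.i.d. uniform payoffs on ``[low, high]``."""
    a, b, c, d = rng.uniform(low, high, size=4)
    return Game(float(a), float(b), float(c), float(d))
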