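"""A deliberately plain direct-method SSA used as an independent oracle.

No delays, no dependency graph, no buffering: every step recomputes every
propensity from a dict of populations.  Kept structurally different from the
package engine on purpose so the two can cross-check each other.
"""

from __future__ import annotations

import math

import numpy as np


class RefReaction:
    """lhs: {species: (stoichiometry, catalyst)}, rhs: {species: stoichiometry}."""

    def __init__(self, lhs: dict, rhs: dict, rate: float):
        self.lhs = lhs
        self.rhs = rhs
        self.rate = rate

    def propensity(self, pops: dict) -> float:
        a = self.rate
        for sp, (stoich, _catalyst) in self.lhs.items():
            n = pops.get(sp, 0)
            if n < stoich:
                return 0.0
            a *= math.comb(n, stoich)
        return a

    def apply(self, pops: dict) -> None:
        for sp, (stoich, catalyst) in self.lhs.items():
            if not catalyst:
                pops[sp] -= stoich
        for sp, stoich in self.rhs.items():
            pops[sp] = pops.get(sp, 0) + stoich


def run_reference(
    reactions: list[RefReaction],
    populations: dict,
    stop_time: float,
    rng: np.random.Generator,
) -> dict:
    """Simulate to ``stop_time`` and return the final populations."""
    pops = dict(populations)
    t = 0.0
    while True:
        props = [rx.propensity(pops) for rx in reactions]
        total = sum(props)
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > stop_time:
            break
        pick = rng.uniform(0.0, total)
        acc = 0.0
        for rx, a in zip(reactions, props):
            acc += a
            if pick <= acc:
                rx.apply(pops)
                break
    return pops
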