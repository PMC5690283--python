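"""Glue between per-trajectory HMM fits and the landscape fit.

At fixed trap separation the dumbbell shares the extension jump between
the protein tether and the DNA handle / trap compliance: the force drops
on unbinding, the handle contracts, and the observed extension change is
smaller than the tether's own change at constant force.  Knowing the
handle elasticity, the observed jump is corrected back to the
constant-force tether frame before the landscape fit:

    dx_tether = dx_obs + x_handle(F_bound) - x_handle(F_unbound)

The per-state mean forces from the idealized trajectories are carried
into the force series so the fit can evaluate unbinding rates at the
bound-state force and binding rates at the unbound-state force, which is
where the dumbbell actually samples them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, Constants
from .hmm import TwoStateHMMFit
from .landscape import ForceSeries
from .polymer import WormLikeChain, wlc_extension

__all__ = ["HMMPoint", "correct_extension_change", "force_series_from_points"]


@dataclass(frozen=True)
class HMMPoint:
    """One trajectory's HMM observables, tagged by molecule and separation."""

    molecule: str
    trap_separation: float
    force_bound: float
    force_unbound: float
    force_mean: float
    p_ub: float
    k_b: float
    k_ub: float
    dx_obs: float


def correct_extension_change(
    dx_obs: float,
    force_bound: float,
    force_unbound: float,
    handle: Optional[WormLikeChain],
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Observed extension jump corrected for handle contraction, nm."""
    if handle is None:
        return dx_obs
    return dx_obs + wlc_extension(handle, force_bound, constants) - wlc_extension(
        handle, force_unbound, constants
    )


def force_series_from_points(
    points: Sequence[HMMPoint],
    handle: Optional[WormLikeChain] = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> List[ForceSeries]:
    """Group per-trajectory observables into per-molecule force series."""
    rows = []
    for p in points:
        rows.append(
            {
                "molecule": p.molecule,
                "trap_sep_nm": p.trap_separation,
                "force_pN": p.force_mean,
                "f_bound_pN": p.force_bound,
                "f_unbound_pN": p.force_unbound,
                "p_ub": p.p_ub,
                "k_b_s": p.k_b,
                "k_ub_s": p.k_ub,
                "dx_nm": correct_extension_change(
                    p.dx_obs, p.force_bound, p.force_unbound, handle, constants
                ),
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for mol, group in frame.groupby("molecule", sort=True):
        out.append(
            ForceSeries(molecule=str(mol), data=group.drop(columns="molecule"))
        )
    return out
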