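"""Test-retest scenario definitions.

A scenario names the subset of samples (session x timepoints) over which
per-probe stability is computed.  Nine scenarios use samples from a single
session; ``CrossSessionT1`` pairs the first draw of both sessions, so its two
"timepoints" are (NoStress, T1) and (Stress, T1) taken one week apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TIMEPOINTS = ("T1", "T2", "T3", "T4")
#: nominal minutes from the first blood draw
TIMEPOINT_MINUTES = {"T1": 0, "T2": 75, "T3": 135, "T4": 285}
SESSIONS = ("NoStress", "Stress")

WEEK_MINUTES = 7 * 24 * 60


@dataclass(frozen=True)
class Scenario:
    """One test-retest scenario.

    ``session_filter`` is ``None`` for the cross-session scenario, in which
    case ``timepoint_list`` holds (session, timepoint) pairs and the repeated
    "occasions" of the crossed model are the sessions' draws themselves.
    """

    name: str
    session_filter: str | None
    timepoint_list: tuple[str, ...]
    interval_minutes: int
    cross_session: bool = field(default=False)

    @property
    def nt(self) -> int:
        return len(self.timepoint_list)

    def select(self, sheet: pd.DataFrame) -> pd.DataFrame:
        """Return the rows of a sample sheet belonging to this scenario.

        The returned frame carries an ``occasion`` column: the level of the
        crossed time random effect (timepoint label, or session label for
        ``CrossSessionT1``).
        """
        if self.cross_session:
            sel = sheet[sheet["timepoint"] == "T1"].copy()
            sel["occasion"] = sel["session"].astype(str)
        else:
            sel = sheet[
                (sheet["session"] == self.session_filter)
                & (sheet["timepoint"].isin(self.timepoint_list))
            ].copy()
            sel["occasion"] = sel["timepoint"].astype(str)
        return sel


def _span(tps: tuple[str, ...]) -> int:
    return TIMEPOINT_MINUTES[tps[-1]] - TIMEPOINT_MINUTES[tps[0]]


def _make_scenarios() -> dict[str, Scenario]:
    out: dict[str, Scenario] = {}
    pairs = [("T1", "T2"), ("T1", "T3"), ("T1", "T4"), ("T3", "T4")]
    for session in SESSIONS:
        for a, b in pairs:
            name = f"{session}{a}-{b[1]}"
            out[name] = Scenario(name, session, (a, b), _span((a, b)))
    out["NoStressT1-2-3-4"] = Scenario(
        "NoStressT1-2-3-4", "NoStress", TIMEPOINTS, _span(TIMEPOINTS)
    )
    out["CrossSessionT1"] = Scenario(
        "CrossSessionT1", None, ("NoStress", "Stress"), WEEK_MINUTES, cross_session=True
    )
    return out


#: the ten scenarios of the study design, keyed by name
SCENARIOS: dict[str, Scenario] = _make_scenarios()

#: scenarios whose stability feeds the highly-stable probe selection
NOSTRESS_AND_CROSS = (
    "NoStressT1-2",
    "NoStressT1-3",
    "NoStressT1-4",
    "NoStressT3-4",
    "NoStressT1-2-3-4",
    "CrossSessionT1",
)

STRESS_SCENARIOS = ("StressT1-2", "StressT1-3", "StressT1-4", "StressT3-4")


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(SCENARIOS)}"
        ) from None
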