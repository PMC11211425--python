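import numpy as np
import pandas as pd
import pytest

import thermex as tx
from thermex import events as ev


def brute_force_flags(series, threshold, direction, min_duration):
    """Independent run-detection oracle: for every day walk outward through
    qualifying neighbours and count the maximal surrounding run."""
    x = np.asarray(series, dtype=float)
    n = x.size

    def qualifies(i):
        if not np.isfinite(x[i]):
            return False
        return x[i] >= threshold if direction == "ge" else x[i] <= threshold

    flags = np.zeros(n, dtype=bool)
    for t in range(n):
        if not qualifies(t):
            continue
        a = t
        while a - 1 >= 0 and qualifies(a - 1):
            a -= 1
        b = t
        while b + 1 < n and qualifies(b + 1):
            b += 1
        if b - a + 1 >= min_duration:
            flags[t] = True
    return flags


def brute_force_classify(day_flags, night_flags):
    out = []
    for d, n in zip(day_flags, night_flags):
        if d and n:
            out.append("compound")
        elif d:
            out.append("daytime_only")
        elif n:
            out.append("nighttime_only")
        else:
            out.append("none")
    return np.array(out, dtype=object)


@pytest.fixture(scope="session")
def heat_panel():
    """One community, 7 years, strong injected compound heat-wave effect."""
    spec = tx.PanelSpec(n_communities=1, years=tuple(range(2007, 2014)), seed=4242)
    mp = tx.MortalityParams(
        event_log_effects={(ev.HEAT_WAVE, "compound"): 0.0849},
        dispersion_target=1.2,
    )
    injection = {ev.HEAT_WAVE: ev.EventDefinition(ev.HEAT_WAVE, 90.0, 2)}
    panels, metadata, truth = tx.simulate_panel(spec, mp=mp, injection=injection)
    panel = panels[0]
    calendar = tx.build_event_calendar(
        panel["date"], panel["tmax"].to_numpy(), panel["tmin"].to_numpy(),
        injection[ev.HEAT_WAVE],
    )
    return panel, calendar, truth


@pytest.fixture(scope="session")
def random_weather():
    """A 3-year weather series for structural tests."""
    return tx.simulate_weather(tx.ClimateParams(), range(2007, 2010), seed=7)
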