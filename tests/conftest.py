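import io

import pytest

from adlwatch.casas_io import (
    pair_activity_instances,
    parse_casas_events,
    write_casas_events,
)
from adlwatch.core import ActivityLabel
from adlwatch.fuzzy import gastro_reference_config
from adlwatch.profiling import build_normal_behavior, group_by_label
from adlwatch.synthetic import (
    default_routine,
    emit_events,
    gastro_episode_scenario,
    generate_routine_instances,
    inject_anomaly_scenario,
)


@pytest.fixture(scope="session")
def gastro_config():
    return gastro_reference_config()


@pytest.fixture(scope="session")
def worked_day_observation():
    """Daily totals of a deviation-period day: every state normal except
    the leaving-home duration (4600 s against a 9000-14400 s range)."""
    return {
        "leaving_home": {"duration": 4600, "frequency": 2},
        "going_to_toilet": {"duration": 2880, "frequency": 12},
        "eating": {"duration": 3720, "frequency": 3},
        "sleeping": {"duration": 32400, "frequency": 2},
    }


@pytest.fixture(scope="session")
def noiseless_world():
    """63-day perfectly regular resident with the 6-day injected episode,
    round-tripped through the event-log format, plus the profile learned
    on the 30-day baseline."""
    spec = default_routine(days=63, seed=7, noiseless=True)
    instances, labels = inject_anomaly_scenario(
        generate_routine_instances(spec), gastro_episode_scenario(), seed=7
    )
    buf = io.StringIO()
    write_casas_events(emit_events(instances), buf)
    buf.seek(0)
    paired = pair_activity_instances(parse_casas_events(buf))
    baseline = [i for i in paired if 0 <= i.day_index < 30]
    behavior = build_normal_behavior(group_by_label(baseline), days=range(30))
    return {
        "spec": spec,
        "instances": paired,
        "labels": labels,
        "behavior": behavior,
        "monitoring": [i for i in paired if i.day_index >= 30],
    }
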