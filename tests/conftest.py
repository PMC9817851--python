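import datetime

import numpy as np
import pandas as pd
import pytest

from follownet.io import DailyRecord, ObservationDataset


def make_daily(date, group, behaviour, identified, dyads):
    """Shorthand DailyRecord constructor for tests."""
    if isinstance(date, int):
        date = datetime.date(2011, 3, 1) + datetime.timedelta(days=date)
    return DailyRecord(
        date=date,
        group_id=group,
        behaviour=behaviour,
        identified_ids=frozenset(identified),
        associated_dyads=frozenset(
            tuple(sorted(pair)) for pair in dyads
        ),
    )


def random_daily_records(rng, ids, n_days, behaviour="proximity", group="G1",
                         p_ident=0.7, p_assoc=0.3):
    """Random daily-record sets used by oracle-equivalence tests."""
    records = []
    for day in range(n_days):
        identified = [i for i in ids if rng.random() < p_ident]
        dyads = set()
        for a in range(len(identified)):
            for b in range(a + 1, len(identified)):
                if rng.random() < p_assoc:
                    dyads.add(tuple(sorted((identified[a], identified[b]))))
        if identified:
            records.append(make_daily(day, group, behaviour, identified, dyads))
    return records


@pytest.fixture
def toy_dataset():
    """Four individuals, one group, three days of follows and events."""
    demographics = pd.DataFrame(
        {
            "id": ["A", "B", "C", "D"],
            "group_id": ["G1"] * 4,
            "origin": ["wild", "wild", "sanctuary", "sanctuary"],
            "sex": ["F", "M", "F", "M"],
            "age_years": [15.0, 20.0, 8.0, 14.0],
            "arrival_age_years": [2.0, 4.0, np.nan, np.nan],
            "rank": [0.5, -0.2, 0.1, -0.4],
            "matriline_id": ["m1", "m2", "m1", "m3"],
        }
    )
    follows = pd.DataFrame(
        {
            "follow_id": ["f1", "f2", "f3", "f4"],
            "focal_id": ["A", "B", "A", "C"],
            "date": [
                datetime.date(2011, 3, 1),
                datetime.date(2011, 3, 1),
                datetime.date(2011, 3, 2),
                datetime.date(2011, 3, 3),
            ],
            "group_id": ["G1"] * 4,
            "in_view_seconds": [600.0, 480.0, 540.0, 360.0],
            "party_member_ids": [("B", "C"), ("A",), ("C", "D"), ()],
        }
    )
    events = pd.DataFrame(
        {
            "date": [
                datetime.date(2011, 3, 1),
                datetime.date(2011, 3, 1),
                datetime.date(2011, 3, 1),
                datetime.date(2011, 3, 2),
                datetime.date(2011, 3, 3),
            ],
            "behaviour": [
                "proximity", "proximity", "proximity", "grooming", "proximity",
            ],
            "id_a": ["A", "A", "B", "A", "C"],
            "id_b": ["B", "B", "A", "C", "D"],
            "group_id": ["G1"] * 5,
        }
    )
    return ObservationDataset.from_frames(follows, events, demographics)
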