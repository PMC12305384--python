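"""End-date imputation, refill stitching, concomitancy, washout."""

from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opioidpgx.exposure import (
    ExposureEpisode,
    PrescriptionRecord,
    concomitant_level,
    impute_end_date,
    inhibitor_free,
    select_first_opioid,
    stitch_episodes,
    stitch_table,
)

D0 = date(2020, 1, 1)


def rx(start_day, quantity, person="p1", drug="hydrocodone", drug_class="opioid",
       strength="not-applicable"):
    return PrescriptionRecord(
        person_id=person,
        drug=drug,
        drug_class=drug_class,
        start_date=D0 + timedelta(days=start_day),
        quantity=quantity,
        inhibitor_strength=strength,
    )


def episode(start_day, end_day, person="p1", drug="fluoxetine",
            drug_class="inhibitor", strength="strong"):
    return ExposureEpisode(
        person_id=person,
        drug=drug,
        drug_class=drug_class,
        start_date=D0 + timedelta(days=start_day),
        end_date=D0 + timedelta(days=end_day),
        source_count=1,
        inhibitor_strength=strength,
    )


class TestImputeEndDate:
    @pytest.mark.parametrize(
        "quantity,end", [(28, date(2020, 1, 7)), (4, date(2020, 1, 1)),
                         (30, date(2020, 1, 8)), (1, date(2020, 1, 1))]
    )
    def test_four_tablets_a_day(self, quantity, end):
        assert impute_end_date(date(2020, 1, 1), quantity) == end

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            impute_end_date(D0, 0)


class TestStitching:
    def _gap_records(self, gap, drug_class="opioid"):
        # rx1 covers days 0..6; rx2 starts so the gap between them is `gap`
        return [
            rx(0, 28, drug_class=drug_class),
            rx(7 + gap, 28, drug_class=drug_class),
        ]

    @pytest.mark.parametrize("gap,n_episodes", [(10, 1), (13, 1), (14, 2)])
    def test_opioid_gap_boundary_under_14(self, gap, n_episodes):
        eps = stitch_episodes(self._gap_records(gap))
        assert len(eps) == n_episodes

    @pytest.mark.parametrize("gap,n_episodes", [(3, 1), (4, 2)])
    def test_inhibitor_gap_boundary_at_3(self, gap, n_episodes):
        eps = stitch_episodes(self._gap_records(gap, drug_class="inhibitor"))
        assert len(eps) == n_episodes

    def test_episode_end_is_last_constituent_end(self):
        eps = stitch_episodes([rx(0, 28), rx(10, 28)])
        assert len(eps) == 1
        assert eps[0].start_date == D0
        assert eps[0].end_date == impute_end_date(D0 + timedelta(days=10), 28)
        assert eps[0].source_count == 2

    def test_mixed_drugs_rejected(self):
        with pytest.raises(ValueError):
            stitch_episodes([rx(0, 28), rx(5, 28, drug="tramadol")])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        starts=st.lists(st.integers(0, 90), min_size=1, max_size=8),
        quantities=st.lists(st.integers(1, 60), min_size=8, max_size=8),
        max_gap=st.sampled_from([3, 13]),
    )
    def test_matches_interval_union_oracle(self, starts, quantities, max_gap):
        records = [rx(s, q) for s, q in zip(starts, quantities)]
        eps = stitch_episodes(records, max_gap_days=max_gap)

        # oracle: mark each covered day, close gaps <= max_gap, read off runs
        intervals = sorted(
            (r.start_date, impute_end_date(r.start_date, r.quantity))
            for r in records
        )
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if (s - merged[-1][1]).days - 1 <= max_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        assert [(e.start_date, e.end_date) for e in eps] == [tuple(m) for m in merged]
        # properties: idempotence-style bounds
        assert len(eps) <= len(records)
        covered_rx = sum((impute_end_date(r.start_date, r.quantity)
                          - r.start_date).days + 1 for r in records)
        covered_ep = sum((e.end_date - e.start_date).days + 1 for e in eps)
        assert covered_ep >= max(
            (impute_end_date(r.start_date, r.quantity) - r.start_date).days + 1
            for r in records
        )
        assert covered_ep <= covered_rx + max_gap * (len(records) - 1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        starts=st.lists(st.integers(0, 90), min_size=1, max_size=8),
        perm=st.randoms(use_true_random=False),
    )
    def test_order_invariant(self, starts, perm):
        records = [rx(s, 20) for s in starts]
        shuffled = list(records)
        perm.shuffle(shuffled)
        assert stitch_episodes(records) == stitch_episodes(shuffled)

    def test_table_stitching_matches_scalar(self, rng):
        rows = []
        for person in range(40):
            n = rng.integers(1, 6)
            drug_class = "inhibitor" if person % 3 == 0 else "opioid"
            for _ in range(n):
                rows.append(
                    {
                        "person_id": person,
                        "drug": "fluoxetine" if drug_class == "inhibitor" else "codeine",
                        "drug_class": drug_class,
                        "inhibitor_strength": "strong" if drug_class == "inhibitor" else "not-applicable",
                        "start_date": pd.Timestamp("2020-01-01")
                        + pd.Timedelta(days=int(rng.integers(0, 120))),
                        "quantity": int(rng.integers(1, 80)),
                    }
                )
        table = pd.DataFrame(rows)
        episodes = stitch_table(table)
        for (person, drug), group in table.groupby(["person_id", "drug"]):
            records = [
                PrescriptionRecord(
                    person, drug, group["drug_class"].iloc[0],
                    r.start_date.date(), int(r.quantity),
                    group["inhibitor_strength"].iloc[0],
                )
                for r in group.itertuples()
            ]
            expected = stitch_episodes(records)
            got = episodes[(episodes.person_id == person) & (episodes.drug == drug)]
            assert len(got) == len(expected)
            for row, exp in zip(got.itertuples(), expected):
                assert row.start_date.date() == exp.start_date
                assert row.end_date.date() == exp.end_date
                assert row.source_count == exp.source_count


class TestConcomitancy:
    def test_three_day_overlap_qualifies(self):
        res = concomitant_level(D0, D0 + timedelta(days=30), [episode(10, 12)])
        assert res.overlap_days == 3
        assert res.level == "strong"

    def test_two_day_overlap_does_not_qualify(self):
        res = concomitant_level(
            D0, D0 + timedelta(days=30), [episode(29, 40, strength="moderate")]
        )
        assert res.overlap_days == 2
        assert res.level == "none"

    def test_strong_dominates_moderate(self):
        res = concomitant_level(
            D0,
            D0 + timedelta(days=30),
            [episode(28, 40, strength="strong"), episode(0, 30, strength="moderate")],
        )
        assert res.level == "strong"
        assert res.overlap_days == 3

    def test_upgrading_strength_never_weakens_level(self, rng):
        order = {"none": 0, "moderate": 1, "strong": 2}
        for _ in range(50):
            s, e = sorted(rng.integers(0, 60, 2))
            moderate = [episode(int(s), int(e), strength="moderate")]
            strong = [episode(int(s), int(e), strength="strong")]
            lvl_m = concomitant_level(D0, D0 + timedelta(days=30), moderate).level
            lvl_s = concomitant_level(D0, D0 + timedelta(days=30), strong).level
            assert order[lvl_s] >= order[lvl_m]


class TestWashout:
    def test_boundaries(self):
        opioid_start = D0 + timedelta(days=400)
        study_end = D0 + timedelta(days=800)
        ended_181_before = [episode(0, 400 - 181)]
        ended_180_before = [episode(0, 400 - 180)]
        assert inhibitor_free(opioid_start, study_end, ended_181_before)
        assert not inhibitor_free(opioid_start, study_end, ended_180_before)
        assert inhibitor_free(opioid_start, study_end, [])

    def test_episode_after_start_also_counts(self):
        opioid_start = D0 + timedelta(days=400)
        study_end = D0 + timedelta(days=800)
        assert not inhibitor_free(opioid_start, study_end, [episode(500, 520)])


class TestFirstOpioid:
    def test_earliest_and_alphabetical_tie_break(self):
        eps = [
            episode(10, 20, drug="tramadol", drug_class="opioid", strength="not-applicable"),
            episode(5, 15, drug="tramadol", drug_class="opioid", strength="not-applicable"),
            episode(5, 25, drug="hydrocodone", drug_class="opioid", strength="not-applicable"),
        ]
        chosen = select_first_opioid(eps)
        assert chosen.drug == "hydrocodone"
        assert chosen.start_date == D0 + timedelta(days=5)

    def test_no_opioid_raises(self):
        with pytest.raises(LookupError):
            select_first_opioid([episode(0, 10)])
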