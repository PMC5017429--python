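"""High-level context engine: store invariants, concurrency queries,
building, inference and change-only high-level notification."""

import numpy as np
import pytest

from mcmine.contexts import (
    ACTIVITIES,
    EMOTIONS,
    LOCATIONS,
    LowLevelContext,
    UNCLASSIFIED,
    default_definitions,
)
from mcmine.fusion import ContextEvent
from mcmine.hlca import (
    ConcurrencyQuery,
    ContextStore,
    HlcaEngine,
    HlcNotifier,
    StoreCorruptionError,
    build_hlc,
    infer,
    map_notification,
)

LABELS = {"activity": ACTIVITIES, "emotion": EMOTIONS, "location": LOCATIONS}


def change(cat, label, t, user="u1"):
    return ContextEvent(user, cat, label, t, "change")


def final(cat, t, user="u1"):
    return ContextEvent(user, cat, None, t, "final")


def interval_scan_oracle(llcs, t, exclude_category=None):
    """Independent O(n) scan under the half-open convention."""
    return [c for c in llcs
            if c.category != exclude_category
            and c.t_start <= t and (c.t_end is None or t < c.t_end)]


class TestMapNotification:
    def test_handover_closes_and_opens(self):
        store = ContextStore()
        map_notification(store, change("activity", "Standing", 0.0))
        map_notification(store, change("activity", "Walking", 10.0))
        closed = [c for c in store.all_llcs("u1") if c.t_end is not None]
        assert closed == [LowLevelContext("u1", "activity", "Standing",
                                          0.0, 10.0)]
        assert store.open_llc("u1", "activity").label == "Walking"

    def test_first_event_opens_without_closing(self):
        store = ContextStore()
        map_notification(store, change("emotion", "Anger", 5.0))
        assert store.open_llc("u1", "emotion").t_start == 5.0
        assert len(store.all_llcs("u1")) == 1

    def test_final_event_closes_only(self):
        store = ContextStore()
        map_notification(store, change("location", "Home", 0.0))
        out = map_notification(store, final("location", 50.0))
        assert out is None
        assert store.open_llc("u1", "location") is None
        closed = store.all_llcs("u1")
        assert closed[0].t_end == 50.0

    def test_store_invariant_under_random_event_streams(self):
        """Never two OPEN contexts per (user, category), whatever the
        event order; checked after every mutation."""
        rng = np.random.default_rng(5)
        store = ContextStore()
        t = 0.0
        for _ in range(300):
            cat = ("activity", "emotion", "location")[rng.integers(0, 3)]
            user = ("u1", "u2")[rng.integers(0, 2)]
            t += float(rng.uniform(0.5, 3.0))
            if rng.uniform() < 0.2:
                map_notification(store, final(cat, t, user))
            else:
                lab = LABELS[cat][rng.integers(0, len(LABELS[cat]))]
                map_notification(store, change(cat, lab, t, user))
            for u in ("u1", "u2"):
                open_counts = {}
                for c in store.all_llcs(u):
                    if c.t_end is None:
                        open_counts[c.category] = \
                            open_counts.get(c.category, 0) + 1
                assert all(v == 1 for v in open_counts.values())


class TestQueryConcurrent:
    def test_open_interval_contains_future_instant(self):
        store = ContextStore()
        map_notification(store, change("emotion", "Anger", 0.0))
        hits = store.query_concurrent(ConcurrencyQuery("u1", 10.0))
        assert [c.label for c in hits] == ["Anger"]

    def test_half_open_boundary_excluded(self):
        store = ContextStore()
        store.store_llc(LowLevelContext("u1", "location", "Home", 0.0, 10.0))
        assert store.query_concurrent(ConcurrencyQuery("u1", 10.0)) == []
        hits = store.query_concurrent(ConcurrencyQuery("u1", 9.999))
        assert len(hits) == 1

    def test_exclude_category(self):
        store = ContextStore()
        map_notification(store, change("activity", "Sitting", 0.0))
        map_notification(store, change("location", "Office", 0.0))
        hits = store.query_concurrent(
            ConcurrencyQuery("u1", 5.0, exclude_category="activity"))
        assert [c.category for c in hits] == ["location"]

    def test_randomized_stores_match_scan_oracle(self):
        """Random interval sets, boundary-heavy query times, vs O(n) scan."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            store = ContextStore()
            llcs = []
            for _ in range(int(rng.integers(1, 25))):
                cat = ("activity", "emotion", "location")[rng.integers(0, 3)]
                lab = LABELS[cat][rng.integers(0, len(LABELS[cat]))]
                t0 = float(rng.integers(0, 20))
                closed = rng.uniform() < 0.8
                t1 = t0 + float(rng.integers(1, 10)) if closed else None
                llc = LowLevelContext("u1", cat, lab, t0, t1)
                llcs.append(llc)
                try:
                    store.store_llc(llc)
                except StoreCorruptionError:
                    llcs.pop()  # second open context of a category
            for _ in range(10):
                t = float(rng.integers(0, 30))  # integer grid hits bounds
                got = store.query_concurrent(ConcurrencyQuery("u1", t))
                expected = interval_scan_oracle(llcs, t)
                assert sorted(got, key=repr) == sorted(expected, key=repr)


class TestBuildAndInfer:
    def test_three_constituent_composition(self):
        a = LowLevelContext("u1", "activity", "Eating", 10.0)
        conc = [LowLevelContext("u1", "emotion", "Happiness", 0.0),
                LowLevelContext("u1", "location", "Restaurant", 0.0)]
        hlc = build_hlc(a, conc)
        assert len(hlc.constituents) == 3
        assert hlc.t_start == 10.0
        assert infer(hlc, default_definitions()).hlc_class == "HavingMeal"

    def test_single_constituent_composition(self):
        a = LowLevelContext("u1", "activity", "Sweeping", 0.0)
        hlc = build_hlc(a, [])
        assert infer(hlc, default_definitions()).hlc_class == UNCLASSIFIED

    def test_sweeping_at_home_is_housework(self):
        a = LowLevelContext("u1", "activity", "Sweeping", 5.0)
        loc = LowLevelContext("u1", "location", "Home", 0.0)
        assert infer(build_hlc(a, [loc]),
                     default_definitions()).hlc_class == "Housework"

    def test_duplicate_category_signals_corruption(self):
        a = LowLevelContext("u1", "activity", "Eating", 0.0)
        other = LowLevelContext("u1", "activity", "Sitting", 0.0)
        with pytest.raises(StoreCorruptionError):
            build_hlc(a, [other])

    def test_invalid_composition_stays_unclassified(self):
        a = LowLevelContext("u1", "activity", "Sitting", 100.0)
        stale = LowLevelContext("u1", "location", "Office", 0.0, 50.0)
        from mcmine.contexts import HighLevelContext
        hlc = HighLevelContext("u1", (a, stale), 100.0)
        assert infer(hlc, default_definitions()).hlc_class == UNCLASSIFIED


class TestHlcNotifier:
    def test_same_class_different_composition_no_event(self):
        engine = HlcaEngine()
        assert engine.on_llc_event(
            change("activity", "Sitting", 0.0)) is not None  # Inactivity
        assert engine.on_llc_event(
            change("location", "Office", 3.0)) is not None   # OfficeWork
        # emotion changes alter the composition but not the class
        assert engine.on_llc_event(change("emotion", "Anger", 6.0)) is None
        assert engine.on_llc_event(change("emotion", "Sadness", 9.0)) is None

    def test_class_change_emits(self):
        engine = HlcaEngine()
        engine.on_llc_event(change("activity", "Sitting", 0.0))
        engine.on_llc_event(change("location", "Office", 3.0))
        ev = engine.on_llc_event(change("activity", "Eating", 60.0))
        assert ev is not None and ev.hlc_class == UNCLASSIFIED

    def test_every_classified_hlc_is_persisted(self):
        engine = HlcaEngine()
        engine.on_llc_event(change("activity", "Sitting", 0.0))
        engine.on_llc_event(change("emotion", "Anger", 3.0))
        engine.on_llc_event(change("emotion", "Neutral", 6.0))
        # three inferences persisted, single notification
        assert len(engine.store.hlcs) == 3
        assert len(engine.events) == 1

    def test_class_events_equal_run_boundaries(self):
        """RLE oracle over the classified class sequence."""
        rng = np.random.default_rng(21)
        notifier = HlcNotifier()
        from mcmine.contexts import HighLevelContext
        stream = [("Inactivity", "OfficeWork", "Exercising")[i]
                  for i in rng.integers(0, 3, size=200)]
        emitted = 0
        for t, cls in enumerate(stream):
            h = HighLevelContext("u1", (), float(t), hlc_class=cls)
            if notifier.notify(h) is not None:
                emitted += 1
        boundaries = 1 + sum(a != b for a, b in zip(stream, stream[1:]))
        assert emitted == boundaries


class TestEmotionRobustness:
    def test_corrupting_emotions_never_changes_the_hlc_timeline(self):
        """With all-ANY emotion definitions, any rewrite of the emotion
        labels in an event stream leaves the class timeline untouched."""
        rng = np.random.default_rng(31)
        events = []
        t = 0.0
        for _ in range(60):
            t += float(rng.uniform(1, 5))
            r = rng.uniform()
            if r < 0.4:
                events.append(change("activity",
                                     ACTIVITIES[rng.integers(0, 8)], t))
            elif r < 0.7:
                events.append(change("location",
                                     LOCATIONS[rng.integers(0, 5)], t))
            else:
                events.append(change("emotion",
                                     EMOTIONS[rng.integers(0, 4)], t))

        def run(evts):
            engine = HlcaEngine()
            for e in evts:
                engine.on_llc_event(e)
            return [(e.hlc_class, e.t) for e in engine.events]

        corrupted = [
            change(e.category, EMOTIONS[(EMOTIONS.index(e.label) + 1) % 4],
                   e.t) if e.category == "emotion" else e
            for e in events
        ]
        assert run(events) == run(corrupted)

    def test_replay_determinism(self):
        """Identical event logs produce identical HLC timelines."""
        events = [change("activity", "Sitting", 0.0),
                  change("location", "Office", 3.0),
                  final("location", 20.0),
                  change("activity", "Running", 30.0)]
        runs = []
        for _ in range(2):
            engine = HlcaEngine()
            for e in events:
                engine.on_llc_event(e)
            runs.append([(e.hlc_class, e.t) for e in engine.events])
        assert runs[0] == runs[1]
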