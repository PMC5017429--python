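"""Context model: validation, definitional classification, config loading."""

import itertools

import pytest

from mcmine.contexts import (
    ACTIVITIES,
    ANY,
    EMOTIONS,
    HLC_CLASSES,
    HighLevelContext,
    HlcDefinition,
    LOCATIONS,
    LowLevelContext,
    UNCLASSIFIED,
    _Any,
    classify_hlc,
    default_definitions,
    default_definitions_path,
    dump_definitions,
    load_definitions,
    validate_hlc,
)


def llc(category, label, t_start=100.0, t_end=None, user="u1"):
    return LowLevelContext(user, category, label, t_start, t_end)


def hlc_of(*llcs, t_start=100.0, user="u1"):
    return HighLevelContext(user, tuple(llcs), t_start)


def brute_force_classify(labels: dict, defs) -> str:
    """Independent matcher: scan definitions in priority order."""
    for d in sorted(defs, key=lambda d: d.priority):
        act = labels.get("activity")
        if act is None or act not in d.required_activities:
            continue
        ok = True
        for cat, allowed in (("location", d.allowed_locations),
                             ("emotion", d.allowed_emotions)):
            if isinstance(allowed, _Any):
                continue
            if labels.get(cat) not in allowed:
                ok = False
                break
        if ok:
            return d.hlc_class
    return UNCLASSIFIED


class TestValidate:
    def test_well_formed_composition_is_valid(self):
        h = hlc_of(llc("activity", "Sitting"), llc("location", "Office"))
        assert validate_hlc(h).valid

    def test_duplicate_category_is_invalid(self):
        h = hlc_of(llc("activity", "Sitting"), llc("activity", "Walking"))
        verdict = validate_hlc(h)
        assert not verdict.valid
        assert "duplicate" in verdict.reason

    def test_non_concurrent_constituent_is_invalid(self):
        # closed before the HLC starts: [50, 90) does not contain t=100
        h = hlc_of(llc("activity", "Sitting"),
                   llc("location", "Office", 50.0, 90.0))
        assert not validate_hlc(h).valid

    def test_interval_containment_is_half_open(self):
        # an interval ending exactly at t_start does not contain it
        h = hlc_of(llc("activity", "Sitting", 0.0, 100.0), t_start=100.0)
        assert not validate_hlc(h).valid
        h2 = hlc_of(llc("activity", "Sitting", 100.0, 100.5), t_start=100.0)
        assert validate_hlc(h2).valid

    def test_mixed_users_invalid(self):
        h = HighLevelContext("u1", (llc("activity", "Sitting", user="u2"),),
                             100.0)
        assert not validate_hlc(h).valid


class TestClassify:
    def test_sitting_at_office_is_office_work(self):
        h = hlc_of(llc("activity", "Sitting"), llc("location", "Office"),
                   llc("emotion", "Neutral"))
        assert classify_hlc(h, default_definitions()) == "OfficeWork"

    def test_eating_at_restaurant_is_having_meal(self):
        h = hlc_of(llc("activity", "Eating"), llc("location", "Restaurant"))
        assert classify_hlc(h, default_definitions()) == "HavingMeal"

    def test_sweeping_at_home_is_housework(self):
        h = hlc_of(llc("activity", "Sweeping"), llc("location", "Home"))
        assert classify_hlc(h, default_definitions()) == "Housework"

    def test_emotion_does_not_change_the_class(self):
        defs = default_definitions()
        got = {classify_hlc(hlc_of(llc("activity", "Sitting"),
                                   llc("location", "Office"),
                                   llc("emotion", e)), defs)
               for e in EMOTIONS}
        assert got == {"OfficeWork"}

    def test_unmatched_composition_is_unclassified(self):
        h = hlc_of(llc("activity", "Walking"))  # Walking needs the Gym
        assert classify_hlc(h, default_definitions()) == UNCLASSIFIED

    def test_empty_defs_rejected(self):
        with pytest.raises(ValueError):
            classify_hlc(hlc_of(llc("activity", "Sitting")), [])

    def test_full_grid_matches_brute_force(self):
        """Exhaustive (activity x location x emotion) grid, absent included."""
        defs = default_definitions()
        for act, loc, emo in itertools.product(
                ACTIVITIES, (*LOCATIONS, None), (*EMOTIONS, None)):
            parts = [llc("activity", act)]
            labels = {"activity": act}
            if loc is not None:
                parts.append(llc("location", loc))
                labels["location"] = loc
            if emo is not None:
                parts.append(llc("emotion", emo))
                labels["emotion"] = emo
            h = hlc_of(*parts)
            assert classify_hlc(h, defs) == brute_force_classify(labels, defs)

    def test_emotion_invariance_over_grid(self):
        """With all-ANY emotions, varying only the emotion never matters."""
        defs = default_definitions()
        for act, loc in itertools.product(ACTIVITIES, (*LOCATIONS, None)):
            parts = [llc("activity", act)]
            if loc is not None:
                parts.append(llc("location", loc))
            base = classify_hlc(hlc_of(*parts), defs)
            for emo in EMOTIONS:
                h = hlc_of(*parts, llc("emotion", emo))
                assert classify_hlc(h, defs) == base

    def test_classification_is_pure(self):
        defs = default_definitions()
        h = hlc_of(llc("activity", "Running"))
        assert classify_hlc(h, defs) == classify_hlc(h, defs) == "Exercising"


class TestDefinitions:
    def test_packaged_config_covers_the_five_classes(self):
        defs = load_definitions(default_definitions_path())
        assert {d.hlc_class for d in defs} == set(HLC_CLASSES)
        assert len({d.priority for d in defs}) == len(defs)

    def test_packaged_config_equals_builtin_defaults(self):
        assert load_definitions(default_definitions_path()) == \
            default_definitions()

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "defs.yaml"
        p.write_text("- {class: Exercising, activities: [Jogging], "
                     "locations: ANY, emotions: ANY, priority: 1}\n")
        with pytest.raises(ValueError, match="Jogging"):
            load_definitions(p)

    def test_duplicate_priority_rejected(self, tmp_path):
        p = tmp_path / "defs.yaml"
        p.write_text(
            "- {class: Exercising, activities: [Running], locations: ANY,"
            " emotions: ANY, priority: 1}\n"
            "- {class: Housework, activities: [Sweeping], locations: ANY,"
            " emotions: ANY, priority: 1}\n")
        with pytest.raises(ValueError, match="unique"):
            load_definitions(p)

    def test_empty_required_activities_rejected(self):
        with pytest.raises(ValueError):
            HlcDefinition("Housework", frozenset(), ANY, ANY, 1)

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "defs.yaml"
        dump_definitions(default_definitions(), p)
        assert load_definitions(p) == default_definitions()


def test_turtle_export(tmp_path):
    from mcmine.contexts import export_turtle
    h = hlc_of(llc("activity", "Sitting"), llc("location", "Office"))
    h.hlc_class = "OfficeWork"
    out = tmp_path / "ctx.ttl"
    export_turtle([h], out)
    text = out.read_text()
    assert "hasActivity" in text and "Sitting" in text
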