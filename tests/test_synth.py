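import pandas as pd
import pytest

from oudharmony.synth import (GeneratorConfig, generate_clean_bundle,
                              inject_errors, who_map)


class TestConfig:
    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(error_rates={"date_year_typo": 1.5})

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=0)


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        a, _ = generate_clean_bundle(GeneratorConfig(n_subjects=6, seed=9))
        b, _ = generate_clean_bundle(GeneratorConfig(n_subjects=6, seed=9))
        for project in a:
            for name in a[project].tables:
                pd.testing.assert_frame_equal(a[project].tables[name],
                                              b[project].tables[name])

    def test_different_seed_differs(self):
        a, _ = generate_clean_bundle(GeneratorConfig(n_subjects=6, seed=9))
        b, _ = generate_clean_bundle(GeneratorConfig(n_subjects=6, seed=10))
        assert not a["CTN-0027"].tables["uds"].equals(b["CTN-0027"].tables["uds"])

    def test_injection_deterministic(self, small_clean):
        c1, l1 = inject_errors(small_clean["bundles"], small_clean["cfg"])
        c2, l2 = inject_errors(small_clean["bundles"], small_clean["cfg"])
        pd.testing.assert_frame_equal(l1, l2)
        for project in c1:
            pd.testing.assert_frame_equal(c1[project].tables["uds"],
                                          c2[project].tables["uds"])


class TestDialectFeatures:
    def test_0051_uses_sows_and_extended_panel(self, small_clean):
        b = small_clean["bundles"]["CTN-0051"]
        assert b.dialect.withdrawal_instrument == "SOWS"
        assays = set(b.tables["uds"]["substance"])
        assert {"BAR", "MDMA"} <= assays
        assert "OPI2000" not in assays

    def test_0027_panel_lacks_buprenorphine(self, small_clean):
        assays = set(small_clean["bundles"]["CTN-0027"].tables["uds"]["substance"])
        assert "BUP" not in assays
        assert {"OPI300", "OPI2000"} <= assays

    def test_0030_rerandomized_subjects_have_two_events(self, clean_run):
        rand = clean_run["bundles"]["CTN-0030"].tables["randomization"]
        two_phase = rand[rand["phase"] == "2"]
        assert len(two_phase) > 0
        truth = clean_run["truth"].tables["randomization"]
        for raw_id in two_phase["ID"]:
            who = who_map(clean_run["bundles"])[("CTN-0030", raw_id)]
            events = truth[truth["who"] == who]
            assert len(events) == 2
            assert events["when"].nunique() == 2

    def test_single_randomization_rows_duplicated(self, clean_run):
        truth = clean_run["truth"]
        enrol = truth.tables["enrollment"]
        rand = truth.tables["randomization"]
        who_27 = set(enrol[enrol["project"] == "CTN-0027"]["who"])
        sub = rand[rand["who"].isin(who_27)]
        for who, g in sub.groupby("who"):
            assert len(g) == 2
            assert g["when"].nunique() == 1  # identical dates, stored twice

    def test_screened_not_randomized_fraction(self, clean_run):
        truth = clean_run["truth"]
        enrolled = set(truth.tables["enrollment"]["who"])
        randomized = set(truth.tables["randomization"]["who"])
        assert randomized < enrolled  # strictly smaller: screened-only exist
        screened_only = enrolled - randomized
        # screened subjects still contribute baseline self-report data
        tlfb_who = set(truth.tables["tlfb"]["who"])
        assert screened_only & tlfb_who


class TestInjection:
    def test_zero_rates_identity_and_empty_ledger(self, small_clean):
        cfg = GeneratorConfig(n_subjects=small_clean["cfg"].n_subjects,
                              seed=small_clean["cfg"].seed,
                              error_rates={})
        corrupted, ledger = inject_errors(small_clean["bundles"], cfg)
        assert len(ledger) == 0
        for project, bundle in small_clean["bundles"].items():
            for name, df in bundle.tables.items():
                pd.testing.assert_frame_equal(df, corrupted[project].tables[name])

    def test_every_rule_represented_at_defaults(self, corrupted_run):
        rules = set(corrupted_run["ledger"]["rule_id"])
        assert {"date_year_typo", "date_offby1", "duplicate_uds",
                "eos_duplicate", "drug_misspelling", "multi_drug_string",
                "dose_other_drug", "drink_amount_missing"} <= rules

    def test_ledger_entries_match_actual_corruptions(self, corrupted_run):
        ledger = corrupted_run["ledger"]
        clean = corrupted_run["clean"]
        corrupted = corrupted_run["corrupted"]
        # year typos: the corrupted date string must appear in the corrupted
        # uds table for that subject and be absent from the clean one
        for _, e in ledger[ledger["rule_id"] == "date_year_typo"].iterrows():
            if e["table"] != "uds":
                continue
            bundle = corrupted[e["project"]]
            dialect = bundle.dialect
            idc = next(c for c in bundle.tables["uds"].columns
                       if c in dialect.id_aliases)
            sub = bundle.tables["uds"]
            dates = set(sub[sub[idc] == e["raw_id"]]["date"])
            clean_dates = set(clean[e["project"]].tables["uds"][
                clean[e["project"]].tables["uds"][idc] == e["raw_id"]]["date"])
            assert dates - clean_dates  # a novel (corrupted) date exists

    def test_misspellings_stay_within_lexicon(self, corrupted_run):
        from oudharmony.textnorm import default_lexicon
        lex = default_lexicon()
        sub = corrupted_run["ledger"]
        sub = sub[sub["rule_id"] == "drug_misspelling"]
        assert len(sub)
        for _, e in sub.iterrows():
            assert lex.variants[e["corrupted_value"]] == e["true_value"]
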