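"""Profile matching, database lookup, passage stability, contamination flags."""

import itertools

import pytest

import strchip as sc


def _mixture_profile(panel, model, cal, prof_a, prof_b, fraction_b, seed):
    per_set = {}
    for set_id in (1, 2, 3, 4):
        trace = sc.simulate_mixture(panel, set_id, prof_a, prof_b, fraction_b,
                                    model, seed + set_id)
        assigned, _ = sc.assign_loci(sc.size_peaks(trace, cal), panel, set_id)
        per_set[set_id] = {
            name: sc.call_alleles(peaks, panel.locus(name))
            for name, peaks in assigned.items()
        }
    return sc.build_profile(per_set, panel, f"{prof_a.label}+{prof_b.label}")


class TestMatchScore:
    def test_self_match_is_one(self, refs):
        for profile in refs.values():
            r = sc.match_score(profile, profile)
            assert r.score == 1.0 and r.verdict == "match"

    def test_hoxb8_1_vs_3_five_shared_alleles(self, refs):
        r = sc.match_score(refs["#1_HoxB8FL"], refs["#3_HoxB8FL"])
        assert r.n_shared == 5
        assert r.n_query_alleles == r.n_ref_alleles == 9
        assert r.score == pytest.approx(10 / 18)
        assert r.verdict == "related"

    def test_hoxb8_1_vs_2_zero_shared(self, refs):
        r = sc.match_score(refs["#1_HoxB8FL"], refs["#2_HoxB8FL"])
        assert r.n_shared == 0 and r.score == 0.0 and r.verdict == "mismatch"

    def test_tanabe_symmetric_masters_not(self, refs):
        for a, b in itertools.combinations(refs.values(), 2):
            assert sc.match_score(a, b).score == sc.match_score(b, a).score
        q, r = refs["mPDAC06"], refs["mPDAC95"]
        mq = sc.match_score(q, r, algorithm="masters_query")
        mr = sc.match_score(q, r, algorithm="masters_ref")
        # different allele totals (14 vs 11) make the two Masters scores differ
        assert mq.n_query_alleles != mq.n_ref_alleles
        assert mq.score != mr.score

    def test_all_fixture_pairs_below_match_threshold(self, refs):
        for a, b in itertools.combinations(refs.values(), 2):
            assert sc.match_score(a, b).score < 0.8

    def test_no_overlap_is_error(self, refs):
        human = sc.synthetic_human_profile()
        with pytest.raises(sc.ProfileError):
            sc.match_score(refs["#1_HoxB8FL"], human)

    def test_human_locus_excluded_with_panel(self, panel, refs):
        query = sc.STRProfile(label="q", alleles={**refs["#1_HoxB8FL"].alleles,
                                                  "D8S1106": (14,)})
        ref = sc.STRProfile(label="r", alleles={**refs["#1_HoxB8FL"].alleles,
                                                "D8S1106": (14,)})
        r = sc.match_score(query, ref, panel=panel)
        assert "D8S1106" not in r.per_locus_shared
        assert r.n_query_alleles == 9


class TestAuthenticateAgainstDb:
    def test_self_in_db_is_best_match(self, refs):
        db = list(refs.values())
        results = sc.authenticate_against_db(refs["#2_HoxB8FL"], db)
        assert results[0].reference_label == "#2_HoxB8FL"
        assert results[0].verdict == "match"
        assert [r.score for r in results] == sorted(
            (r.score for r in results), reverse=True)

    def test_pdac_lines_never_match_each_other(self, refs):
        pdac = [refs[k] for k in ("mPDAC06", "mPDAC09", "mPDAC95")]
        for query in pdac:
            others = [p for p in pdac if p.label != query.label]
            results = sc.authenticate_against_db(query, others)
            assert all(r.verdict != "match" for r in results)

    def test_single_locus_query_still_ranked(self, refs):
        query = sc.STRProfile(label="partial", alleles={"9-2": (17,)})
        results = sc.authenticate_against_db(query, list(refs.values()))
        assert results[0].score == 1.0
        assert results[0].reference_label == "#1_HoxB8FL"

    def test_empty_db_is_error(self, refs):
        with pytest.raises(sc.ProfileError):
            sc.authenticate_against_db(refs["#1_HoxB8FL"], [])


class TestPassageStability:
    def test_noisy_replicates_are_stable(self, panel, model, refs):
        """P5 / P15 / post-cryo emulation: same line, different noise seeds."""
        profiles = []
        for seed in (101, 102, 103):
            ladder, wells = sc.simulate_sample_wells(panel, refs["#2_HoxB8FL"],
                                                     model, seed)
            profiles.append(sc.call_sample(ladder, wells, panel, "#2_HoxB8FL"))
        report = sc.check_passage_stability(profiles)
        assert report.stable and report.discordant_loci == ()

    def test_shifted_allele_reported(self, refs):
        drifted = sc.STRProfile(label="late", alleles={
            **refs["#1_HoxB8FL"].alleles, "9-2": (18,)})
        report = sc.check_passage_stability([refs["#1_HoxB8FL"], drifted])
        assert not report.stable
        assert report.discordant_loci == ("9-2",)

    def test_single_profile_is_error(self, refs):
        with pytest.raises(sc.ProfileError):
            sc.check_passage_stability([refs["#1_HoxB8FL"]])


class TestInterspecies:
    def test_mixture_raises_flag(self, panel, model, calibration, refs):
        mix = sc.simulate_mixture(panel, 2, refs["#1_HoxB8FL"],
                                  sc.synthetic_human_profile(), 0.5, model, 11)
        report = sc.detect_interspecies(sc.size_peaks(mix, calibration), panel)
        assert report.interspecies_flag and report.species == "mixed"

    def test_pure_samples_do_not(self, panel, model, calibration, refs):
        mouse = sc.simulate_sample_trace(panel, 2, refs["#1_HoxB8FL"], model, 12)
        rm = sc.detect_interspecies(sc.size_peaks(mouse, calibration), panel)
        assert not rm.interspecies_flag and rm.species == "mouse"
        human = sc.simulate_sample_trace(panel, 2, sc.synthetic_human_profile(),
                                         model, 13)
        rh = sc.detect_interspecies(sc.size_peaks(human, calibration), panel)
        assert not rh.interspecies_flag and rh.species == "human"

    def test_profile_input(self, panel, refs):
        report = sc.detect_interspecies(refs["#1_HoxB8FL"], panel)
        assert not report.interspecies_flag and report.species == "mouse"


class TestIntraspecies:
    def test_murine_mixture_flagged_with_db(self, panel, model, calibration, refs):
        mix = _mixture_profile(panel, model, calibration, refs["#1_HoxB8FL"],
                               refs["#3_HoxB8FL"], 0.5, seed=20)
        report = sc.detect_intraspecies(mix, reference_db=list(refs.values()),
                                        panel=panel)
        assert report.intraspecies_flag
        # the two lines differ at exactly these loci
        assert set(report.supporting_loci) == {"9-2", "12-1", "5-5", "X-1"}
        assert report.secondary_profile.label == "#3_HoxB8FL"

    def test_clean_profile_not_flagged(self, panel, refs):
        for profile in refs.values():
            report = sc.detect_intraspecies(profile,
                                            reference_db=list(refs.values()),
                                            panel=panel)
            assert not report.intraspecies_flag

    def test_threshold_above_panel_size_never_flags(self, panel, model,
                                                    calibration, refs):
        mix = _mixture_profile(panel, model, calibration, refs["#1_HoxB8FL"],
                               refs["#3_HoxB8FL"], 0.5, seed=20)
        report = sc.detect_intraspecies(mix, min_extra_loci=10,
                                        reference_db=list(refs.values()),
                                        panel=panel)
        assert not report.intraspecies_flag

    def test_extra_allele_flags_count(self, refs):
        noisy = sc.STRProfile(
            label="tri", alleles={**refs["#1_HoxB8FL"].alleles},
            locus_flags={"9-2": frozenset({"extra_allele"}),
                         "5-5": frozenset({"extra_allele"})})
        report = sc.detect_intraspecies(noisy, min_extra_loci=2)
        assert report.intraspecies_flag
        assert report.supporting_loci == ["5-5", "9-2"]

    def test_mixture_flag_monotone_in_fraction(self, panel, model, calibration,
                                               refs):
        flags = []
        for f in (0.2, 0.3, 0.5):
            mix = _mixture_profile(panel, model, calibration, refs["#1_HoxB8FL"],
                                   refs["#3_HoxB8FL"], f, seed=30)
            flags.append(sc.detect_intraspecies(
                mix, reference_db=list(refs.values()), panel=panel
            ).intraspecies_flag)
        # once flagged at some fraction, every larger fraction stays flagged
        assert flags == sorted(flags)
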