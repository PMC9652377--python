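"""Ensemble triage: energy filter, orientation filter, clustering, representatives."""

import math
import random

import numpy as np
import pytest

from quests import (
    DimerGeometry,
    EnsembleRecord,
    TriageConfig,
    apply_orientation_filter,
    cluster_models,
    energy_filter,
    run_triage,
    select_representatives,
)
from quests.ensemble import records_from_tsv, records_to_frame
from quests.fixtures import ClusterSpec, EnsembleSpec, make_dimer_ensemble
from tests.conftest import two_cluster_spec


def simple_records(energies, thetas=None):
    thetas = thetas if thetas is not None else [52.0] * len(energies)
    return [
        EnsembleRecord(
            model_id=f"m{i:04d}",
            geometry=DimerGeometry(theta=t, d=12.0, angle_tm5=t),
            interface_energy=e,
        )
        for i, (e, t) in enumerate(zip(energies, thetas))
    ]


class TestEnergyFilter:
    def test_keeps_the_lowest_tenth(self):
        records = simple_records(list(range(1, 101)))
        energy_filter(records, 0.10)
        kept = sorted(r.interface_energy for r in records if r.kept_energy)
        assert kept == list(range(1, 11))

    def test_fraction_one_keeps_all(self):
        records = simple_records([3.0, 1.0, 2.0])
        energy_filter(records, 1.0)
        assert all(r.kept_energy for r in records)

    @pytest.mark.parametrize("n,fraction,expected", [(95, 0.10, 10), (100, 0.10, 10), (7, 0.5, 4)])
    def test_count_is_ceiling_of_fraction(self, n, fraction, expected):
        records = simple_records(list(np.linspace(0, 1, n)))
        energy_filter(records, fraction)
        assert sum(r.kept_energy for r in records) == expected
        assert expected == math.ceil(fraction * n)

    def test_ties_broken_by_model_id(self):
        records = simple_records([1.0, 1.0, 1.0, 1.0])
        energy_filter(records, 0.25)
        assert [r.kept_energy for r in records] == [True, False, False, False]

    def test_missing_energy_raises(self):
        records = simple_records([1.0, 2.0])
        records[1].interface_energy = None
        with pytest.raises(ValueError, match="missing interface energies"):
            energy_filter(records, 0.1)

    def test_order_independent(self):
        records = simple_records(list(np.linspace(5, -5, 50)))
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        energy_filter(records, 0.2)
        expected = {r.model_id: r.kept_energy for r in records}
        energy_filter(shuffled, 0.2)
        assert {r.model_id: r.kept_energy for r in shuffled} == expected


class TestOrientationFilter:
    def test_planted_out_of_window_fraction_is_exact(self):
        records, truth = make_dimer_ensemble(two_cluster_spec(n_models=1000, seed=7, outside=0.20))
        _, kept_fraction = apply_orientation_filter(records)
        assert kept_fraction == pytest.approx(0.80, abs=1e-12)
        # and the filter flags exactly the planted models
        flagged = np.array([not r.kept_orientation for r in records])
        assert (flagged == truth["outside"]).all()

    def test_all_at_crystallographic_angle_kept(self):
        records = simple_records([1.0] * 10, thetas=[52.0] * 10)
        _, kept_fraction = apply_orientation_filter(records)
        assert kept_fraction == 1.0

    def test_empty_energy_kept_set_flagged(self):
        records = simple_records([1.0, 2.0])
        for r in records:
            r.kept_energy = False
        with pytest.warns(UserWarning, match="undefined"):
            _, kept_fraction = apply_orientation_filter(records)
        assert kept_fraction is None


class TestClustering:
    def test_recovers_two_planted_conformations(self, planted_two_cluster_ensemble):
        records, truth = planted_two_cluster_ensemble
        _, summaries = cluster_models(records)
        labels = np.array([r.cluster for r in records])
        assert len(summaries) == 2
        # majority mapping between found labels and planted components
        agree = 0
        for found in (0, 1):
            members = truth["cluster"][labels == found]
            agree += np.bincount(members, minlength=2).max()
        assert agree / len(records) >= 0.95

    def test_single_tight_blob_is_one_cluster_no_noise(self):
        # "tight" = geometric spread negligible against the feature scale;
        # a finite-spread unimodal Gaussian legitimately sheds tail points
        # as noise under excess-of-mass selection, so the trivial case is
        # the degenerate blob
        spec = EnsembleSpec(
            clusters=[ClusterSpec(1.0, 52.0, 0.0, 12.0, 0.0, -30.0, 1.0)],
            n_models=200,
            seed=3,
        )
        records, _ = make_dimer_ensemble(spec)
        _, summaries = cluster_models(records)
        assert len(summaries) == 1
        assert all(r.cluster == 0 for r in records)

    def test_single_gaussian_blob_is_one_cluster(self):
        spec = EnsembleSpec(
            clusters=[ClusterSpec(1.0, 52.0, 1.0, 12.0, 0.3, -30.0, 1.0)],
            n_models=200,
            seed=3,
        )
        records, _ = make_dimer_ensemble(spec)
        _, summaries = cluster_models(records)
        assert len(summaries) == 1

    def test_uniform_scatter_is_mostly_noise(self):
        rng = np.random.default_rng(21)
        records = simple_records(
            list(rng.normal(size=50)),
            thetas=list(rng.uniform(-49, 84, 50)),
        )
        for r, d in zip(records, rng.uniform(5, 60, 50)):
            r.geometry = DimerGeometry(theta=r.theta, d=float(d), angle_tm5=r.theta)
        _, summaries = cluster_models(records, min_cluster_size=25)
        n_noise = sum(1 for r in records if r.cluster == -1)
        # no dense structure: at least half the points are noise and no
        # cluster holds a majority of the data
        assert n_noise >= 25
        assert all(s.size <= 25 for s in summaries)

    def test_too_few_points_fall_back_to_single_cluster(self):
        records = simple_records([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="fallback"):
            _, summaries = cluster_models(records, min_cluster_size=10)
        assert len(summaries) == 1 and summaries[0].size == 3

    def test_label_assignment_stable_under_shuffling(self, planted_two_cluster_ensemble):
        records, _ = planted_two_cluster_ensemble
        cluster_models(records)
        reference = {r.model_id: r.cluster for r in records}
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        cluster_models(shuffled)
        assert {r.model_id: r.cluster for r in shuffled} == reference


class TestRepresentatives:
    def test_minimum_population_cutoff(self):
        records, _ = make_dimer_ensemble(two_cluster_spec(n_models=499, seed=13))
        # plant a singleton far from both conformations: 1/500 = 0.2 %
        records.append(
            EnsembleRecord("zzz_lone", DimerGeometry(-40.0, 40.0, -40.0), interface_energy=-50.0)
        )
        records, summaries = cluster_models(records, min_cluster_size=5)
        survivors = select_representatives(records, summaries, min_population=0.02)
        labels = {s.label for s in survivors}
        lone = [r for r in records if r.model_id == "zzz_lone"][0]
        assert lone.cluster not in labels
        assert select_representatives(records, summaries, min_population=0.0) == summaries

    def test_representative_is_cluster_energy_argmin(self, planted_two_cluster_ensemble):
        records, _ = planted_two_cluster_ensemble
        records, summaries = cluster_models(records)
        for s in summaries:
            members = [r for r in records if r.cluster == s.label]
            assert s.representative_energy == min(r.interface_energy for r in members)
            assert all(s.representative_energy <= r.interface_energy for r in members)


class TestRunTriage:
    def test_end_to_end_recovers_planted_conformations(self):
        records, _ = make_dimer_ensemble(
            two_cluster_spec(n_models=2000, seed=29, outside=0.10)
        )
        report = run_triage(records, TriageConfig(energy_fraction=0.5))
        assert len(report.representatives) == 2
        open_like, closed_like = sorted(
            report.representatives, key=lambda s: -s.population_fraction
        )
        # the open-like conformation was planted with 70 % weight
        assert abs(open_like.centroid_theta - 52.0) < 3.0
        assert open_like.population_fraction > closed_like.population_fraction

    def test_all_models_failing_orientation_gives_empty_representatives(self):
        records = simple_records([1.0] * 20, thetas=[120.0] * 20)
        report = run_triage(records)
        assert report.representatives == []
        assert "no_models_pass_filters" in report.flags

    def test_rerun_is_byte_identical(self):
        spec = two_cluster_spec(n_models=400, seed=31)
        r1, _ = make_dimer_ensemble(spec)
        r2, _ = make_dimer_ensemble(spec)
        assert run_triage(r1).to_json() == run_triage(r2).to_json()

    def test_pooling_multiple_sets(self):
        half1, _ = make_dimer_ensemble(two_cluster_spec(n_models=200, seed=1))
        half2, _ = make_dimer_ensemble(two_cluster_spec(n_models=200, seed=2))
        report = run_triage([half1, half2], TriageConfig(energy_fraction=1.0))
        assert len(report.records) == 400


def test_tsv_round_trip(tmp_path):
    records, _ = make_dimer_ensemble(two_cluster_spec(n_models=50, seed=4))
    path = tmp_path / "ensemble.tsv"
    records_to_frame(records)[["model_id", "theta", "d", "energy"]].to_csv(
        path, sep="\t", index=False
    )
    reread = records_from_tsv(path)
    assert [r.model_id for r in reread] == [r.model_id for r in records]
    np.testing.assert_allclose([r.theta for r in reread], [r.theta for r in records])
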