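"""Generator contracts: reproducibility, planted structure, artifact embedding."""

import numpy as np
import pytest
from scipy import stats

from somnofuse.core import ConfigurationError, DataError
from somnofuse.design import DesignMatrix
from somnofuse.synth import (
    ArtifactModel,
    CohortSpec,
    GROUPS,
    LABEL_IDS,
    PlantedEffect,
    SpectralEffect,
    default_effect_table,
    embed_gradient_artifact,
    embed_pulse_artifact,
    generate_bold,
    iter_subjects,
    make_label_volume,
    sensor_positions,
    simulate_band_share_tables,
    simulate_cohort,
    simulate_events,
    subject_band_shares,
)

SMALL = dict(session_duration=120.0, n_channels=16, eeg_rate=250.0)


class TestCohortSpec:
    def test_default_group_sizes(self):
        spec = CohortSpec()
        assert (spec.n_controls, spec.n_patients) == (8, 9)
        cohort = simulate_cohort(spec, with_eeg=False, with_bold=False)
        groups = [s.group for s in cohort.subjects]
        assert groups.count("control") == 8 and groups.count("patient") == 9

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_controls", 0),
            ("tr", 0.0),
            ("eeg_rate", 30.0),
            ("session_duration", 5.0),
            ("grid_shape", (2, 2, 2)),
        ],
    )
    def test_invalid_spec_names_field(self, field, value):
        spec = CohortSpec(**{field: value})
        with pytest.raises(ConfigurationError):
            spec.validate()

    def test_planted_effect_guards(self):
        with pytest.raises(ConfigurationError):
            PlantedEffect("precuneus", "alpha", "control", 0, 2.0)  # sign 0, amp != 0
        with pytest.raises(ConfigurationError):
            PlantedEffect("nowhere", "alpha", "control", 1, 1.0)


class TestReproducibility:
    def test_fixed_seed_bit_identical(self):
        spec = CohortSpec(seed=7, **SMALL)
        a = next(iter_subjects(spec))
        b = next(iter_subjects(spec))
        np.testing.assert_array_equal(a.eeg.signal, b.eeg.signal)
        np.testing.assert_array_equal(a.bold.data, b.bold.data)
        assert a.events.frame.equals(b.events.frame)

    def test_seed_changes_data(self):
        a = next(iter_subjects(CohortSpec(seed=7, **SMALL), with_eeg=False))
        b = next(iter_subjects(CohortSpec(seed=8, **SMALL), with_eeg=False))
        assert not np.array_equal(a.bold.data, b.bold.data)


class TestBandShares:
    def test_shares_sum_to_one(self, rng):
        shares = subject_band_shares(CohortSpec(), "patient", rng)
        for state in ("baseline", "A", "T"):
            np.testing.assert_allclose(shares[state].sum(axis=1), 1.0, atol=1e-9)

    def test_planted_alpha_effect_detectable(self):
        """Planted d=2.0 on 10 electrodes: the two-sample t on the
        generator's own A-epoch share table exceeds |t|>2 in >=90% of
        seeds (direct t-test oracle on the emitted table)."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            spec = CohortSpec(
                seed=1000 + seed,
                spectral_effect=SpectralEffect(effect_size_d=2.0, n_electrodes=10),
            )
            tables = simulate_band_share_tables(spec, "A")
            pe = tables["planted_electrodes"]
            t, _ = stats.ttest_ind(
                tables["control"][:, pe, 2].mean(axis=1),
                tables["patient"][:, pe, 2].mean(axis=1),
            )
            hits += abs(t) > 2
        assert hits >= 0.9 * n_seeds

    def test_zero_effect_alpha_means_not_systematically_different(self):
        """With effect amplitudes at zero the two groups' alpha shares are
        drawn from the same distribution: across independent cohorts the
        group difference t-statistic rejects at ~the nominal rate."""
        rejections = 0
        n_cohorts = 40
        for k in range(n_cohorts):
            spec = CohortSpec(
                seed=4000 + k, spectral_effect=SpectralEffect(effect_size_d=0.0))
            tables = simulate_band_share_tables(spec, "A")
            t, p = stats.ttest_ind(
                tables["control"][:, :, 2].mean(axis=1),
                tables["patient"][:, :, 2].mean(axis=1))
            rejections += p < 0.05
        assert rejections <= 6  # ~2 expected at the nominal 5% level


class TestEvents:
    def test_every_subject_has_both_conditions(self, rng):
        for group in GROUPS:
            ev = simulate_events(CohortSpec(), group, rng)
            assert len(ev.for_condition("A")) >= 1
            assert len(ev.for_condition("T")) >= 1
            assert len(ev.for_condition("wake")) == 1

    def test_epochs_do_not_overlap(self, rng):
        ev = simulate_events(CohortSpec(session_duration=600.0), "control", rng)
        rows = ev.frame.sort_values("onset")
        ends = (rows["onset"] + rows["duration"]).to_numpy()[:-1]
        starts = rows["onset"].to_numpy()[1:]
        assert np.all(starts >= ends - 1e-9)

    def test_durations_within_bounds(self, rng):
        ev = simulate_events(CohortSpec(session_duration=900.0), "patient", rng)
        at = ev.frame[ev.frame["condition"].isin(["A", "T"])]
        assert at["duration"].between(2.0, 15.0).all()


class TestGenerateBold:
    def _tiny_design(self, n=20, k=3, seed=0):
        g = np.random.default_rng(seed)
        X = np.column_stack([g.standard_normal((n, k - 1)), np.ones(n)])
        return DesignMatrix(
            X, names=[f"c{i}" for i in range(k - 1)] + ["intercept"],
            roles=["condition"] * (k - 1) + ["intercept"], tr=1.0)

    def test_zero_noise_identity(self):
        design = self._tiny_design()
        betas = np.arange(8 * 3, dtype=float).reshape(8, 3)
        vol = generate_bold(design, betas, 0.0, (2, 2, 2), 1.0)
        Y = vol.data.reshape(8, -1).T
        recovered, *_ = np.linalg.lstsq(design.matrix, Y, rcond=None)
        np.testing.assert_allclose(recovered.T, betas, atol=1e-10)

    def test_zero_betas_noise_means_near_baseline(self):
        design = self._tiny_design(n=300)
        betas = np.zeros((200, 3))
        vol = generate_bold(design, betas, 1.0, (10, 5, 4), 1.0,
                            rng=np.random.default_rng(1))
        means = vol.data.mean(axis=3).ravel()
        # SEM = 1/sqrt(300); +-0.2 is ~3.5 SEM
        assert np.mean(np.abs(means) <= 0.2) >= 0.95

    def test_shape_mismatch_raises(self):
        design = self._tiny_design()
        with pytest.raises(Exception):
            generate_bold(design, np.zeros((7, 3)), 0.0, (2, 2, 2), 1.0)

    def test_default_effect_table_signs_planted(self, light_subject):
        """The secondary-visual-cortex alpha coupling is + for controls
        and - for patients in the planted betas."""
        spec = CohortSpec(seed=9)
        labels = make_label_volume(spec.grid_shape).reshape(-1)
        svc = labels == LABEL_IDS["secondary_visual_cortex"]
        # light_subject is a control subject
        assert light_subject.group == "control"
        names = light_subject.truth.true_design.names
        col = names.index("blp_alpha")
        assert np.all(light_subject.truth.true_betas[svc, col] > 0)
        patient = [s for s in simulate_cohort(spec, with_eeg=False).subjects
                   if s.group == "patient"][0]
        assert np.all(patient.truth.true_betas[svc, col] < 0)

    def test_sign_zero_cells_have_zero_betas(self):
        table = default_effect_table()
        zero = [e for e in table if e.coupling_sign == 0]
        assert zero and all(e.coupling_amplitude == 0 for e in zero)


class TestGradientArtifact:
    def _eeg(self, seed=0, n_ch=4, n=6000, rate=250.0):
        from somnofuse.core import EEGRecording

        g = np.random.default_rng(seed)
        pos, labels = sensor_positions(n_ch)
        return EEGRecording(g.standard_normal((n_ch, n)), rate, labels, pos)

    def test_zero_amplitude_is_identity_with_triggers(self):
        eeg = self._eeg()
        onsets = np.arange(10) * 250 + 100
        tmpl = np.ones((4, 250))
        out = embed_gradient_artifact(eeg, onsets, tmpl, amplitude=0.0)
        np.testing.assert_array_equal(out.signal, eeg.signal)
        assert len(out.event_samples("volume_trigger")) == 10

    def test_tr_spacing_in_samples(self):
        spec = CohortSpec(seed=0, **SMALL)
        subj = next(iter_subjects(spec))
        triggers = subj.eeg.event_samples("volume_trigger")
        assert np.all(np.diff(triggers) == int(spec.tr * spec.eeg_rate))

    def test_epoch_average_recovers_template(self):
        """Epoch-averaging contaminated-minus-clean over many epochs gives
        back the embedded template exactly (planted periodicity oracle)."""
        eeg = self._eeg(n=40 * 250 + 500)
        onsets = 100 + np.arange(35) * 250
        g = np.random.default_rng(5)
        tmpl = g.standard_normal((4, 250)) * 50
        out = embed_gradient_artifact(eeg, onsets, tmpl)
        diff = out.signal - eeg.signal
        epochs = np.stack([diff[:, s : s + 250] for s in onsets])
        np.testing.assert_allclose(epochs.mean(axis=0), tmpl, atol=1e-9)

    def test_out_of_bounds_onset_raises(self):
        eeg = self._eeg(n=1000)
        with pytest.raises(DataError):
            embed_gradient_artifact(eeg, np.array([900]), np.ones((4, 250)))


class TestPulseArtifact:
    def _eeg(self, duration=60.0, rate=250.0, n_ch=4):
        from somnofuse.core import EEGRecording

        pos, labels = sensor_positions(n_ch)
        return EEGRecording(
            np.zeros((n_ch, int(duration * rate))), rate, labels, pos)

    def test_60bpm_plants_60_beats(self):
        eeg = self._eeg(61.0)
        onsets = np.arange(60) * 1.0 + 0.2
        tmpl = np.ones((4, 100))
        out, scales = embed_pulse_artifact(eeg, onsets, tmpl, per_beat_scale_sd=0.0)
        assert scales.size == 60
        # each beat leaves a nonzero footprint
        assert np.count_nonzero(out.signal[0]) == 60 * 100

    def test_zero_scale_sd_beat_average_equals_template(self):
        eeg = self._eeg(120.0)
        onsets = np.arange(100) * 1.0 + 0.5
        g = np.random.default_rng(2)
        tmpl = g.standard_normal((4, 150))
        out, _ = embed_pulse_artifact(eeg, onsets, tmpl, per_beat_scale_sd=0.0)
        starts = np.round(onsets * eeg.rate).astype(int)
        epochs = np.stack([out.signal[:, s : s + 150] for s in starts])
        np.testing.assert_allclose(epochs.mean(axis=0), tmpl, atol=1e-9)

    def test_scale_recovery_by_projection(self, rng):
        """Per-beat least-squares fit of the template to the planted
        component recovers the drawn scales (linear projection oracle)."""
        eeg = self._eeg(120.0)
        onsets = np.arange(100) * 1.0 + 0.5
        tmpl = rng.standard_normal((4, 150))
        out, scales = embed_pulse_artifact(
            eeg, onsets, tmpl, per_beat_scale_sd=0.2, rng=rng)
        starts = np.round(onsets * eeg.rate).astype(int)
        flat_t = tmpl.ravel()
        est = np.array([
            out.signal[:, s : s + 150].ravel() @ flat_t / (flat_t @ flat_t)
            for s in starts
        ])
        assert np.sqrt(np.mean((est - scales) ** 2)) <= 0.02

    def test_template_longer_than_beat_interval_rejected(self):
        eeg = self._eeg(30.0)
        onsets = np.arange(20) * 0.6 + 0.2
        with pytest.raises(ConfigurationError):
            embed_pulse_artifact(eeg, onsets, np.ones((4, 200)))


class TestAdditiveDecomposition:
    def test_contaminated_equals_clean_plus_components(self, default_subject):
        truth = default_subject.truth
        n = default_subject.eeg.n_samples
        total = (
            truth.clean_eeg.signal
            + truth.gradient_component(n)
            + truth.pulse_component(n)
            + truth.blink_component()
        )
        np.testing.assert_allclose(default_subject.eeg.signal, total, atol=1e-9)


class TestLabelsAndSensors:
    def test_label_volume_has_all_regions(self):
        vol = make_label_volume((12, 14, 12))
        present = set(np.unique(vol))
        assert present == set(LABEL_IDS.values())

    def test_regions_disjoint_and_nonempty(self):
        vol = make_label_volume((12, 14, 12))
        for name, lid in LABEL_IDS.items():
            if name == "background":
                continue
            assert (vol == lid).sum() >= 16

    def test_sensor_positions_unit_sphere_and_mastoids(self):
        pos, labels = sensor_positions(32)
        assert labels[-2:] == ["M1", "M2"]
        radii = np.linalg.norm(pos[:-2], axis=1)
        np.testing.assert_allclose(radii, 1.0, atol=1e-9)
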