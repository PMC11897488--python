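import numpy as np
import pytest

from topobrain.cohort import (
    DOSENBACH_NETWORKS,
    CohortSpec,
    CohortSpecError,
    PanelFormatError,
    generate_cohort,
    read_panel,
    write_panel,
)


def small_spec(**kw):
    base = dict(n_subjects_per_group=4, networks={"A": 6}, n_timepoints=80,
                seed=3)
    base.update(kw)
    return CohortSpec(**base)


def mean_within_network_r(panel, network, group):
    rs = []
    for s in panel.subjects_in_group(group):
        X = panel.subject_matrix(s, network)
        r = np.corrcoef(X)
        rs.append(r[np.triu_indices(len(r), 1)].mean())
    return float(np.mean(rs))


def test_default_partition_is_the_six_network_parcellation():
    spec = CohortSpec()
    assert spec.networks == DOSENBACH_NETWORKS
    assert sum(spec.networks.values()) == 160


def test_same_seed_gives_bit_identical_panels():
    a = generate_cohort(small_spec())
    b = generate_cohort(small_spec())
    assert np.array_equal(a.values, b.values)
    assert a.subject_ids == b.subject_ids and a.roi_ids == b.roi_ids


def test_different_seed_changes_the_panel():
    a = generate_cohort(small_spec())
    b = generate_cohort(small_spec(seed=4))
    assert not np.array_equal(a.values, b.values)


def test_groups_are_balanced_and_labelled():
    panel = generate_cohort(small_spec())
    assert len(panel.subjects_in_group("HC")) == 4
    assert len(panel.subjects_in_group("MCI")) == 4
    assert all(panel.roi_network[r] == "A" for r in panel.roi_ids)


def test_planted_coupling_shift_raises_within_network_correlation():
    """The documented planted-effect configuration: MCI coupling 0.3 above HC.

    The emitted arrays are checked by direct correlation recomputation."""
    spec = CohortSpec(n_subjects_per_group=20, networks={"A": 8},
                      n_timepoints=150, coupling_base=0.3,
                      coupling_shift_per_group={"HC": 0.0, "MCI": 0.3},
                      seed=1)
    panel = generate_cohort(spec)
    r_hc = mean_within_network_r(panel, "A", "HC")
    r_mci = mean_within_network_r(panel, "A", "MCI")
    assert r_mci > r_hc
    # coupling c times mean mixing alignment: MCI roughly doubles HC
    assert r_mci > 1.5 * r_hc


def test_null_configuration_has_no_group_gap():
    """With all shifts zero the group gap is pure sampling noise.

    Average the within-network correlation gap over 20 seeds; under the null
    it is centred at zero with a per-seed s.d. well under 0.03, so the mean
    over 20 seeds stays within 0.02 except with negligible probability.
    """
    gaps = []
    for seed in range(20):
        spec = small_spec(coupling_shift_per_group={"HC": 0.0, "MCI": 0.0},
                          seed=seed)
        panel = generate_cohort(spec)
        gaps.append(mean_within_network_r(panel, "A", "MCI")
                    - mean_within_network_r(panel, "A", "HC"))
    assert abs(np.mean(gaps)) < 0.02


def test_effect_is_monotone_in_the_coupling_shift():
    gaps = []
    for shift in (0.0, 0.15, 0.3):
        per_seed = []
        for seed in range(5):
            spec = small_spec(
                coupling_shift_per_group={"HC": 0.0, "MCI": shift}, seed=seed)
            panel = generate_cohort(spec)
            per_seed.append(mean_within_network_r(panel, "A", "MCI")
                            - mean_within_network_r(panel, "A", "HC"))
        gaps.append(np.mean(per_seed))
    assert gaps[0] <= gaps[1] <= gaps[2]


@pytest.mark.parametrize("field, value, msg", [
    ("n_subjects_per_group", 0, "n_subjects_per_group"),
    ("ar_coefficient", 1.0, "ar_coefficient"),
    ("driver_ar_coefficient", -1.5, "driver_ar_coefficient"),
    ("coupling_base", 0.9, "coupling_base"),  # 0.9 + 0.3 shift > 1
    ("noise_sd", 0.0, "noise_sd"),
    ("latent_rank", 0, "latent_rank"),
])
def test_invalid_spec_error_names_the_field(field, value, msg):
    spec = CohortSpec(**{field: value})
    with pytest.raises(CohortSpecError, match=msg):
        spec.validate()


def test_missing_group_shift_is_rejected():
    spec = CohortSpec(groups=("HC", "EMCI", "LMCI"))
    with pytest.raises(CohortSpecError, match="EMCI"):
        spec.validate()


class TestPanelIO:
    def test_round_trip_identity(self, tmp_path):
        panel = generate_cohort(small_spec())
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        back = read_panel(path)
        assert back.subject_ids == panel.subject_ids
        assert back.roi_ids == panel.roi_ids
        assert back.subject_group == panel.subject_group
        assert back.roi_network == panel.roi_network
        assert np.allclose(back.values, panel.values, atol=1e-8)

    def test_file_shape_matches_panel_shape(self, tmp_path):
        spec = small_spec(n_subjects_per_group=1, groups=("HC", "MCI"),
                          networks={"A": 3}, n_timepoints=5)
        panel = generate_cohort(spec)  # 2 subjects x 3 ROIs x 5 timepoints
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1 + 6  # header + 2*3 data rows
        assert len(lines[1].split("\t")) == 2 + 5  # labels + 5 value columns

    def test_sidecar_missing_roi_is_named(self, tmp_path):
        panel = generate_cohort(small_spec())
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        import json
        sidecar = json.loads((tmp_path / "panel.json").read_text())
        del sidecar["roi_network"]["A_003"]
        (tmp_path / "panel.json").write_text(json.dumps(sidecar))
        with pytest.raises(PanelFormatError, match="A_003"):
            read_panel(path)

    def test_duplicate_rows_are_rejected(self, tmp_path):
        panel = generate_cohort(small_spec())
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        lines = path.read_text().rstrip("\n").split("\n")
        lines.append(lines[1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PanelFormatError, match="duplicate"):
            read_panel(path)
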