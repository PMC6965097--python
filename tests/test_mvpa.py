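import numpy as np
import pytest

from lexnet import mvpa


def make_tc(rng, n_runs=2, trials_per_run=4, n_vox=8, n_trs=60):
    """Hand-built RoiTimecourse: trials of 10 TRs separated by null gaps."""
    values = rng.normal(size=(n_runs * n_trs, n_vox))
    run = np.repeat(np.arange(n_runs), n_trs)
    trial = np.full(n_runs * n_trs, -1)
    cond = np.full(n_runs * n_trs, "null", dtype=object)
    cells = list(mvpa.CELLS)
    t_id = 0
    for r in range(n_runs):
        for i in range(trials_per_run):
            start = r * n_trs + 2 + i * 12
            trial[start:start + 10] = t_id
            cond[start:start + 10] = cells[t_id % 4]
            t_id += 1
    return mvpa.RoiTimecourse(values, run, trial, np.asarray(cond, dtype=str))


# ---------------------------------------------------------------------------
# domain types


def test_timecourse_rejects_bad_labels():
    rng = np.random.default_rng(0)
    tc = make_tc(rng)
    bad = tc.condition_labels.copy()
    bad[0] = "mystery"
    with pytest.raises(ValueError):
        mvpa.RoiTimecourse(tc.values, tc.run_labels, tc.trial_labels, bad)


def test_timecourse_rejects_short_trial():
    rng = np.random.default_rng(0)
    tc = make_tc(rng)
    trial = tc.trial_labels.copy()
    trial[np.flatnonzero(trial == 0)[0]] = -1  # trial 0 now spans 9 TRs
    with pytest.raises(ValueError):
        mvpa.RoiTimecourse(tc.values, tc.run_labels, trial, tc.condition_labels)


def test_timecourse_tsv_round_trip(tmp_path):
    tc = make_tc(np.random.default_rng(1))
    tc.to_tsv(tmp_path / "tc.tsv")
    back = mvpa.RoiTimecourse.from_tsv(tmp_path / "tc.tsv")
    assert np.allclose(back.values, tc.values)
    assert (back.condition_labels == tc.condition_labels).all()
    assert (back.trial_labels == tc.trial_labels).all()


def test_evidence_series_tsv_round_trip_keeps_null(tmp_path):
    ev = mvpa.EvidenceSeries(np.array([0.7, np.nan, 0.4]),
                             np.array(["word", "null", "nonword"]),
                             np.zeros(3, dtype=int))
    ev.to_tsv(tmp_path / "ev.tsv")
    back = mvpa.EvidenceSeries.from_tsv(tmp_path / "ev.tsv")
    assert (back.condition == ev.condition).all()
    assert np.isnan(back.evidence[1]) and back.evidence[0] == 0.7


def test_evidence_series_rejects_out_of_range():
    with pytest.raises(ValueError):
        mvpa.EvidenceSeries(np.array([1.0]), np.array(["word"]), np.zeros(1))
    with pytest.raises(ValueError):
        mvpa.EvidenceSeries(np.array([np.nan]), np.array(["word"]), np.zeros(1))


# ---------------------------------------------------------------------------
# preprocessing


def test_savgol_preserves_cubic_exactly():
    # a cubic per run is invariant under order-3 Savitzky-Golay smoothing,
    # so preprocessing reduces to plain per-run z-scoring
    t = np.arange(60, dtype=float)
    cubic = 0.1 * t ** 3 - 2 * t ** 2 + t + 5
    values = np.stack([cubic, cubic[::-1]], axis=1)
    tc = make_tc(np.random.default_rng(2), n_runs=1, n_vox=2)
    tc = mvpa.RoiTimecourse(values, tc.run_labels, tc.trial_labels,
                            tc.condition_labels)
    z = mvpa.preprocess_per_tr(tc)[0]
    expected = (values - values.mean(axis=0)) / values.std(axis=0)
    assert np.allclose(z, expected, atol=1e-8)


def test_zscore_moments_per_run():
    tc = make_tc(np.random.default_rng(3), n_runs=3)
    z = mvpa.preprocess_per_tr(tc)[0]
    for r in range(3):
        rows = tc.run_labels == r
        assert np.allclose(z[rows].mean(axis=0), 0, atol=1e-10)
        assert np.allclose(z[rows].std(axis=0), 1, atol=1e-10)


def test_zero_variance_voxel_warns_and_zeroes():
    tc = make_tc(np.random.default_rng(4), n_runs=1)
    values = tc.values.copy()
    values[:, 0] = 7.0
    tc = mvpa.RoiTimecourse(values, tc.run_labels, tc.trial_labels,
                            tc.condition_labels)
    with pytest.warns(UserWarning, match="zero-variance"):
        z = mvpa.preprocess_per_tr(tc)[0]
    assert (z[:, 0] == 0).all()


def test_run_shorter_than_window_rejected():
    rng = np.random.default_rng(5)
    values = rng.normal(size=(15, 3))
    tc_kwargs = dict(run_labels=np.zeros(15, dtype=int),
                     trial_labels=np.full(15, -1),
                     condition_labels=np.full(15, "null"))
    tc = mvpa.RoiTimecourse(values, **tc_kwargs)
    with pytest.raises(ValueError, match="smoothing window"):
        mvpa.preprocess_per_tr(tc)


def test_label_shift_moves_labels_later():
    tc = make_tc(np.random.default_rng(6), n_runs=1, trials_per_run=1)
    z, letters, conds = mvpa.preprocess_per_tr(tc)
    src = np.flatnonzero(tc.trial_labels == 0)
    assert (letters[src + mvpa.HRF_SHIFT_TRS] != "null").all()
    assert letters[src[0]] == "null"  # label no longer at stimulus onset
    tps = mvpa.preprocess_timecourses(tc)
    assert np.allclose(tps.patterns[0], z[src + mvpa.HRF_SHIFT_TRS].mean(axis=0))


def test_preprocess_trial_bookkeeping():
    tc = make_tc(np.random.default_rng(7), n_runs=2, trials_per_run=4)
    tps = mvpa.preprocess_timecourses(tc)
    assert len(tps) == 8
    assert set(np.unique(tps.letter)) == {"U", "N"}
    assert set(np.unique(tps.condition)) == {"word", "nonword"}
    assert (np.bincount(tps.run) == 4).all()


# ---------------------------------------------------------------------------
# voxel selection


def test_topk_counts_and_tie_break():
    z = np.array([1.0, 1.0, 1.0, 0.5, 2.0])
    idx = mvpa.select_voxels(z, "topk", k=3)
    assert set(idx) == {0, 1, 4}  # ties broken by lowest index


def test_topk_bounds():
    with pytest.raises(ValueError):
        mvpa.select_voxels(np.ones(5), "topk", k=6)
    with pytest.raises(ValueError):
        mvpa.select_voxels(np.ones(5), "topk", k=0)
    with pytest.raises(ValueError):
        mvpa.select_voxels(np.array([1.0, np.nan]), "topk", k=1)


def test_peripheral_intersection():
    rng = np.random.default_rng(8)
    main = rng.normal(size=100)
    loc = rng.normal(size=100)
    idx = mvpa.select_voxels(main, "peripheral", localiser_zstats=loc)
    assert (main[idx] >= np.median(main)).all()
    assert (loc[idx] <= np.median(loc)).all()
    assert not np.isin(np.flatnonzero(loc > np.median(loc)), idx).any()


def test_voxel_selectivity_flags_informative_voxel():
    rng = np.random.default_rng(9)
    patterns = rng.normal(size=(40, 5))
    letter = np.array(["U", "N"] * 20)
    patterns[letter == "U", 2] += 4.0
    tps = mvpa.TrialPatternSet(patterns, letter,
                               np.full(40, "word"), np.zeros(40, dtype=int))
    sel = mvpa.voxel_selectivity(tps)
    assert np.argmax(sel) == 2


# ---------------------------------------------------------------------------
# decoding and evidence


def _separable_set(rng, n=40, n_vox=6, gap=3.0, condition=None):
    letter = np.array(["U", "N"] * (n // 2))
    patterns = rng.normal(size=(n, n_vox))
    patterns[letter == "U", 0] += gap
    cond = condition if condition is not None else np.array(
        ["word", "nonword"] * (n // 2))
    return mvpa.TrialPatternSet(patterns, letter, cond,
                                np.zeros(n, dtype=int))


def test_classifier_perfect_on_separable():
    rng = np.random.default_rng(10)
    loc = _separable_set(rng, gap=6.0)
    clf = mvpa.train_letter_classifier(loc)
    test = _separable_set(rng, gap=6.0)
    acc = mvpa.decode_by_condition(clf, test)
    assert acc["word"] == acc["nonword"] == acc["overall"] == 1.0


def test_classifier_label_swap_negates_weights():
    rng = np.random.default_rng(11)
    loc = _separable_set(rng)
    swapped = mvpa.TrialPatternSet(loc.patterns,
                                   np.where(loc.letter == "U", "N", "U"),
                                   loc.condition, loc.run)
    a = mvpa.train_letter_classifier(loc)
    b = mvpa.train_letter_classifier(swapped)
    assert np.allclose(a.weights, -b.weights, atol=1e-4)
    assert np.isclose(a.intercept, -b.intercept, atol=1e-4)


def test_classifier_chance_on_noise():
    rng = np.random.default_rng(12)
    loc = _separable_set(rng, n=200, gap=0.0)
    clf = mvpa.train_letter_classifier(loc)
    test = _separable_set(np.random.default_rng(13), n=400, gap=0.0)
    acc = mvpa.decode_by_condition(clf, test)
    assert 0.35 < acc["overall"] < 0.65


def test_classifier_requires_both_classes_and_matching_voxels():
    rng = np.random.default_rng(14)
    loc = _separable_set(rng)
    only_u = mvpa.TrialPatternSet(loc.patterns, np.full(len(loc), "U"),
                                  loc.condition, loc.run)
    with pytest.raises(ValueError):
        mvpa.train_letter_classifier(only_u)
    clf = mvpa.train_letter_classifier(loc)
    with pytest.raises(ValueError, match="voxel dimension"):
        clf.scores(np.ones((3, loc.n_voxels + 1)))


def test_evidence_series_definition():
    clf = mvpa.LetterClassifier(weights=np.zeros(4), intercept=0.0)
    patterns = np.random.default_rng(15).normal(size=(6, 4))
    letters = np.array(["U", "N", "U", "null", "N", "U"])
    conds = np.array(["word", "word", "nonword", "null", "nonword", "word"])
    ev = mvpa.evidence_series(clf, patterns, letters, conds, np.zeros(6))
    live = conds != "null"
    assert np.allclose(ev.evidence[live], 0.5)  # zero decoder -> p = 1/2
    assert np.isnan(ev.evidence[3])
    # a biased decoder gives complementary evidence for U and N
    clf2 = mvpa.LetterClassifier(weights=np.zeros(4), intercept=1.0)
    ev2 = mvpa.evidence_series(clf2, patterns, letters, conds, np.zeros(6))
    p = 1 / (1 + np.exp(-1.0))
    assert np.allclose(ev2.evidence[letters == "U"], p)
    assert np.allclose(ev2.evidence[(letters == "N") & live], 1 - p)


# ---------------------------------------------------------------------------
# pattern-correlation information


def test_pattern_info_constructed_case():
    rng = np.random.default_rng(16)
    base_u = rng.normal(size=12)
    base_n = -base_u  # anticorrelated letter patterns
    rows, letters, conds = [], [], []
    for letter, base in (("U", base_u), ("N", base_n)):
        for cond in mvpa.CONDITIONS:
            for _ in range(4):
                rows.append(base)
                letters.append(letter)
                conds.append(cond)
    tps = mvpa.TrialPatternSet(np.array(rows), np.array(letters),
                               np.array(conds), np.zeros(len(rows), dtype=int))
    info = mvpa.pattern_correlation_info(tps, n_repeats=3,
                                         rng=np.random.default_rng(17))
    for c in mvpa.CONDITIONS:
        assert np.isclose(info[c].rho_within, 1.0)
        assert np.isclose(info[c].rho_between, -1.0)
        assert np.isclose(info[c].score, 2.0)


def test_pattern_info_null_is_near_zero():
    rng = np.random.default_rng(18)
    n = 96
    tps = mvpa.TrialPatternSet(
        rng.normal(size=(n, 30)),
        np.array(["U", "N"] * (n // 2)),
        np.array(["word"] * (n // 2) + ["nonword"] * (n // 2)),
        np.zeros(n, dtype=int))
    info = mvpa.pattern_correlation_info(tps, n_repeats=24,
                                         rng=np.random.default_rng(19))
    for c in mvpa.CONDITIONS:
        assert abs(info[c].score) < 0.5


def test_pattern_info_requires_two_trials_per_cell():
    tps = mvpa.TrialPatternSet(np.ones((3, 4)), np.array(["U", "N", "N"]),
                               np.array(["word", "word", "nonword"]),
                               np.zeros(3, dtype=int))
    with pytest.raises(ValueError, match="fewer than 2"):
        mvpa.pattern_correlation_info(tps, n_repeats=2)


# ---------------------------------------------------------------------------
# searchlight


def _grid_coords(shape=(7, 7, 7), voxel_mm=2.0):
    idx = np.indices(shape).reshape(3, -1).T
    return idx * voxel_mm


def test_sphere_members_matches_lattice_enumeration():
    coords = _grid_coords()
    centre = 3 * 49 + 3 * 7 + 3  # the central voxel of the 7x7x7 grid
    members = mvpa.sphere_members(coords, centre, 6.0)
    # 2 mm grid, 6 mm radius -> lattice points with dx^2+dy^2+dz^2 <= 9
    expected = sum(1 for dx in range(-3, 4) for dy in range(-3, 4)
                   for dz in range(-3, 4) if dx * dx + dy * dy + dz * dz <= 9)
    assert expected == 123
    assert len(members) == 123
    d = np.linalg.norm(coords[members] - coords[centre], axis=1)
    assert (d <= 6.0).all()


def test_sphere_members_truncates_at_edges():
    coords = _grid_coords()
    members = mvpa.sphere_members(coords, 0, 6.0)
    assert len(members) < 123
    assert 0 in members


def test_searchlight_validates_radius_and_shape():
    coords = _grid_coords((2, 2, 2))
    rng = np.random.default_rng(20)
    tps = _separable_set(rng, n_vox=8)
    with pytest.raises(ValueError, match="radius"):
        mvpa.searchlight_map(coords, tps, tps, radius_mm=1.0)
    with pytest.raises(ValueError, match="voxel axis"):
        mvpa.searchlight_map(coords[:4], tps, tps)


def test_searchlight_decode_scores_informative_region():
    rng = np.random.default_rng(21)
    coords = _grid_coords((3, 3, 3))
    n_vox = 27
    letter = np.array(["U", "N"] * 20)
    loc = rng.normal(size=(40, n_vox))
    main = rng.normal(size=(40, n_vox))
    loc[letter == "U", 0] += 5.0  # only voxel 0 is informative
    main[letter == "U", 0] += 5.0
    kw = dict(letter=letter, condition=np.array(["word", "nonword"] * 20),
              run=np.zeros(40, dtype=int))
    sl = mvpa.searchlight_map(coords, mvpa.TrialPatternSet(loc, **kw),
                              mvpa.TrialPatternSet(main, **kw), radius_mm=2.0)
    assert sl[0] > 0.95
    assert sl[26] < 0.8  # opposite corner excludes voxel 0


# ---------------------------------------------------------------------------
# univariate amplitude control


def test_univariate_amplitude_exact_recovery():
    rng = np.random.default_rng(22)
    tc = make_tc(rng, n_runs=2, n_vox=5)
    n = tc.values.shape[0]
    X = rng.normal(size=(n, 4))
    names = list(mvpa.CELLS)
    beta_true = np.array([2.0, -1.0, 0.5, 3.0])
    y = X @ beta_true + 4.0
    values = np.tile(y[:, None], (1, 5))
    tc = mvpa.RoiTimecourse(values, tc.run_labels, tc.trial_labels,
                            tc.condition_labels)
    amp = mvpa.univariate_amplitude(tc, X, names)
    for name, b in zip(names, beta_true):
        assert abs(amp[name] - b) < 1e-8


def test_univariate_amplitude_names_collinear_column():
    rng = np.random.default_rng(23)
    tc = make_tc(rng, n_runs=1, n_vox=2)
    n = tc.values.shape[0]
    X = rng.normal(size=(n, 2))
    X[:, 1] = X[:, 0]  # duplicate regressor
    with pytest.raises(ValueError, match="U-nonword"):
        mvpa.univariate_amplitude(tc, X, ["U-word", "U-nonword"])


def test_roi_size_sweep_shape():
    rng = np.random.default_rng(24)
    loc = _separable_set(rng, n_vox=20)
    main = _separable_set(rng, n_vox=20)
    z = mvpa.voxel_selectivity(loc)
    df = mvpa.roi_size_sweep(z, loc, main, ks=[5, 10, 20])
    assert list(df["k"]) == [5, 10, 20]
    assert set(df.columns) == {"k", "word", "nonword", "overall"}
    assert df["overall"].between(0, 1).all()
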