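import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pirfish as pf
from pirfish.fish import (classify_spots, detect_spots, match_spots,
                          mitosis_counts, project_max, quantify_cells,
                          quantify_field, segment_nuclei)
from pirfish.synth.images import PlacementError, SignalTruth


# ---------------------------------------------------------------------------
# projection


def test_projection_of_constant_stack_is_plane():
    stack = np.full((5, 8, 9), 7.0)
    assert np.array_equal(project_max(stack), np.full((8, 9), 7.0))


def test_projection_keeps_bright_voxel_position():
    stack = np.zeros((4, 10, 10))
    stack[2, 3, 7] = 99
    proj = project_max(stack)
    assert proj[3, 7] == 99 and proj.sum() == 99


def test_projection_rejects_2d_input():
    with pytest.raises(ValueError):
        project_max(np.zeros((5, 5)))


def test_projection_maxima_at_rendered_spot_positions():
    field = pf.simulate_field(n_signals=2, n_cells=1, snr=1e6, seed=1,
                              class_probs=(0.0, 1.0, 0.0))
    proj = project_max(field.exon).astype(float)
    for s in field.truth.signals:
        _, y, x = s.exon_zyx
        yi, xi = int(round(y)), int(round(x))
        win = proj[yi - 2:yi + 3, xi - 2:xi + 3]
        assert win.max() == win[2, 2] or win.max() >= proj.mean() + 5


# ---------------------------------------------------------------------------
# detection


def test_blank_image_yields_no_spots():
    rng = np.random.default_rng(0)
    img = rng.normal(200, 20, size=(256, 256))
    assert len(detect_spots(img)) == 0


def test_non_finite_pixels_rejected():
    img = np.zeros((32, 32))
    img[3, 3] = np.nan
    with pytest.raises(ValueError):
        detect_spots(img)


def test_single_spot_found_within_one_pixel():
    field = pf.simulate_field(n_signals=1, n_cells=1, snr=10.0, seed=2,
                              class_probs=(0.0, 1.0, 0.0))
    truth = field.truth.signals[0].exon_zyx
    spots = detect_spots(project_max(field.exon))
    assert len(spots) == 1
    assert abs(spots.at[0, "y"] - truth[1]) <= 1.0
    assert abs(spots.at[0, "x"] - truth[2]) <= 1.0


def test_dense_field_recall_and_precision(snr5_field):
    spots = detect_spots(snr5_field.exon, sigma=(1.0, 1.3, 1.3))
    truth = np.array([s.exon_zyx[1:] for s in snr5_field.truth.signals
                      if s.exon_zyx is not None])
    from scipy.spatial import cKDTree
    d, _ = cKDTree(spots[["y", "x"]].to_numpy()).query(truth)
    recall = np.mean(d <= 2.0)
    d2, _ = cKDTree(truth).query(spots[["y", "x"]].to_numpy())
    precision = np.mean(d2 <= 2.0)
    assert recall >= 0.95 and precision >= 0.95


# ---------------------------------------------------------------------------
# segmentation


def test_three_nuclei_recovered_with_accurate_areas():
    field = pf.simulate_field(n_cells=3, n_signals=0, seed=3)
    labels = segment_nuclei(field.dna)
    found = np.unique(labels)
    assert len(found[found > 0]) == 3
    true_areas = sorted(np.sum(field.truth.nucleus_mask == c)
                        for c in (1, 2, 3))
    est_areas = sorted(np.sum(labels == c) for c in found[found > 0])
    for t, e in zip(true_areas, est_areas):
        assert abs(e - t) / t <= 0.10


def test_empty_dna_image_gives_no_labels():
    assert segment_nuclei(np.zeros((64, 64))).max() == 0


def test_provided_mask_passthrough():
    mask = np.arange(16).reshape(4, 4)
    out = segment_nuclei(np.zeros((4, 4)), provided_mask=mask)
    assert out is not None and np.array_equal(out, mask)


# ---------------------------------------------------------------------------
# matching


def spots_df(points):
    return pd.DataFrame(points, columns=["y", "x"], dtype=float)


def test_pair_within_radius_matches():
    m = match_spots(spots_df([(10, 10)]), spots_df([(11, 10)]), radius=3)
    assert m.pairs == [(0, 0)] and not m.unmatched_exon


def test_far_intron_becomes_solo():
    m = match_spots(spots_df([(10, 10)]), spots_df([(20, 10)]), radius=3)
    assert m.pairs == [] and m.unmatched_intron == [0]


def test_equidistant_tie_gives_one_pair_to_smaller_index():
    m = match_spots(spots_df([(10, 9), (10, 11)]), spots_df([(10, 10)]),
                    radius=3)
    assert m.pairs == [(0, 0)]
    assert m.unmatched_exon == [1]


def test_negative_radius_rejected():
    with pytest.raises(ValueError):
        match_spots(spots_df([(0, 0)]), spots_df([(0, 0)]), radius=-1)


@given(st.data())
def test_count_conservation_and_radius_monotonicity(data):
    n_e = data.draw(st.integers(0, 15))
    n_i = data.draw(st.integers(0, 15))
    coords = st.tuples(st.floats(0, 50), st.floats(0, 50))
    exon = spots_df(data.draw(st.lists(coords, min_size=n_e, max_size=n_e)))
    intron = spots_df(data.draw(st.lists(coords, min_size=n_i, max_size=n_i)))
    r1, r2 = sorted([data.draw(st.floats(0, 10)), data.draw(st.floats(0, 10))])
    m1 = match_spots(exon, intron, radius=r1)
    m2 = match_spots(exon, intron, radius=r2)
    for m in (m1, m2):
        assert len(m.pairs) + len(m.unmatched_exon) == len(exon)
        assert len(m.pairs) + len(m.unmatched_intron) == len(intron)
    assert set(m1.pairs) <= set(m2.pairs)


@pytest.mark.parametrize("seed", range(5))
def test_pair_count_equals_maximum_matching_on_separated_spots(seed):
    """On resolvable fields greedy mutual-NN matching is maximum-cardinality."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    rng = np.random.default_rng(seed)
    # well-separated anchors, a random subset paired within the radius
    anchors = []
    while len(anchors) < 20:
        p = rng.uniform(10, 190, size=2)
        if all(np.hypot(*(p - a)) > 8 for a in anchors):
            anchors.append(p)
    exon, intron = [], []
    for a in anchors:
        kind = rng.random()
        if kind < 0.5:
            exon.append(a)
            intron.append(a + rng.uniform(-1.5, 1.5, size=2))
        elif kind < 0.8:
            exon.append(a)
        else:
            intron.append(a)
    exon, intron = spots_df(exon), spots_df(intron)
    m = match_spots(exon, intron, radius=3.0)
    rowsc, cols = [], []
    for i in range(len(exon)):
        for j in range(len(intron)):
            d = np.hypot(exon.at[i, "y"] - intron.at[j, "y"],
                         exon.at[i, "x"] - intron.at[j, "x"])
            if d <= 3.0:
                rowsc.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rowsc)), (rowsc, cols)),
                       shape=(len(exon), len(intron)))
    optimum = int((maximum_bipartite_matching(graph, "column") >= 0).sum())
    assert len(m.pairs) == optimum


# ---------------------------------------------------------------------------
# per-cell quantification


def test_nuclear_pir_arithmetic():
    nucleus = np.ones((20, 20), dtype=int)
    cell = np.ones((20, 20), dtype=int)
    rows = ([{"signal_class": "unspliced_pair", "y": 5, "x": y}
             for y in range(9)]
            + [{"signal_class": "spliced_exon_only", "y": 7, "x": 3}])
    quant = quantify_cells(pd.DataFrame(rows), nucleus, cell)
    assert quant.at[0, "exon_nuclear"] == 10
    assert quant.at[0, "nuclear_pir"] == pytest.approx(90.0)


def test_empty_nucleus_gives_undefined_pir():
    nucleus = np.zeros((10, 10), dtype=int)
    cell = np.ones((10, 10), dtype=int)
    sig = pd.DataFrame([{"signal_class": "spliced_exon_only", "y": 4, "x": 4}])
    quant = quantify_cells(sig, nucleus, cell)
    assert np.isnan(quant.at[0, "nuclear_pir"])
    assert quant.at[0, "nuclear_enrichment"] == 0.0


def test_solo_introns_excluded_from_transcript_totals():
    nucleus = np.ones((10, 10), dtype=int)
    cell = np.ones((10, 10), dtype=int)
    sig = pd.DataFrame([
        {"signal_class": "unspliced_pair", "y": 2, "x": 2},
        {"signal_class": "solo_intron", "y": 5, "x": 5},
    ])
    quant = quantify_cells(sig, nucleus, cell)
    assert quant.at[0, "exon_total"] == 1
    assert quant.at[0, "solo_intron"] == 1


def test_spots_outside_cells_dropped_with_count():
    cell = np.zeros((10, 10), dtype=int)
    cell[:5] = 1
    sig = pd.DataFrame([
        {"signal_class": "spliced_exon_only", "y": 2, "x": 2},
        {"signal_class": "spliced_exon_only", "y": 8, "x": 8},
    ])
    quant = quantify_cells(sig, np.zeros_like(cell), cell)
    assert quant.attrs["n_dropped"] == 1
    assert quant.at[0, "exon_total"] == 1


def test_end_to_end_counts_exact_on_clean_field():
    field = pf.simulate_field(n_signals=40, snr=20.0, seed=5)
    quant = quantify_field(field.exon, field.intron,
                           nucleus_mask=field.truth.nucleus_mask,
                           cell_mask=field.truth.cell_mask)
    truth = field.truth.per_cell_truth()
    merged = quant.merge(truth, on="cell_id", suffixes=("", "_true"))
    for col in ("unspliced_nuclear", "spliced_nuclear", "solo_intron",
                "exon_total", "exon_nuclear"):
        assert (merged[col] == merged[f"{col}_true"]).all(), col


def test_end_to_end_nuclear_pir_recovery(snr5_field):
    quant = quantify_field(snr5_field.exon, snr5_field.intron,
                           nucleus_mask=snr5_field.truth.nucleus_mask,
                           cell_mask=snr5_field.truth.cell_mask)
    truth = snr5_field.truth.per_cell_truth()
    merged = quant.merge(truth, on="cell_id", suffixes=("", "_true"))
    err = (merged["nuclear_pir"] - merged["nuclear_pir_true"]).abs().dropna()
    assert (err <= 3.0).mean() >= 0.90


# ---------------------------------------------------------------------------
# mitosis


def cellquant_row(cid, mitotic, unspliced, spliced, solo):
    return {"cell_id": cid, "mitotic": mitotic,
            "unspliced_nuclear": unspliced, "unspliced_cytoplasmic": 0,
            "spliced_nuclear": spliced, "spliced_cytoplasmic": 0,
            "solo_intron": solo}


def test_all_interphase_no_mitosis_rows():
    df = pd.DataFrame([cellquant_row(1, False, 3, 1, 0),
                       cellquant_row(2, False, 5, 2, 0)])
    out = mitosis_counts(df)
    assert set(out["stage"]) == {"interphase"}


def test_mitotic_cells_with_only_spliced_and_solo():
    df = pd.DataFrame([cellquant_row(1, False, 10, 4, 0),
                       cellquant_row(2, True, 0, 9, 8),
                       cellquant_row(3, True, 0, 10, 9)])
    out = mitosis_counts(df).set_index(["stage", "variable"])
    assert out.loc[("mitosis", "unspliced"), "mean"] == 0.0
    assert out.loc[("mitosis", "solo_intron"), "mean"] == pytest.approx(8.5)


def test_planted_stage_means_recovered():
    rng = np.random.default_rng(0)
    rows = [cellquant_row(i, False, int(rng.poisson(10)), 4, 0)
            for i in range(30)]
    rows += [cellquant_row(100 + i, True, int(rng.poisson(1)), 9, 8)
             for i in range(30)]
    out = mitosis_counts(pd.DataFrame(rows)).set_index(["stage", "variable"])
    assert out.loc[("interphase", "unspliced"), "mean"] == pytest.approx(
        10, abs=2.0)
    assert out.loc[("mitosis", "unspliced"), "mean"] == pytest.approx(
        1, abs=0.8)


# ---------------------------------------------------------------------------
# synthetic image generator contracts


def test_same_seed_byte_identical_field_files(tmp_path):
    dirs = []
    for name in ("a", "b"):
        field = pf.simulate_field(n_signals=30, seed=7)
        d = tmp_path / name
        field.write(d)
        dirs.append(d)
    for fname in ("exon.tif", "intron.tif", "dna.tif", "nucleus_mask.tif",
                  "truth_cells.tsv", "params.json"):
        assert (dirs[0] / fname).read_bytes() == (dirs[1] / fname).read_bytes()


def test_truth_invariants_validated_on_emission():
    field = pf.simulate_field(n_signals=25, seed=8)
    field.truth.validate()  # must not raise
    with pytest.raises(ValueError):
        SignalTruth("spliced_exon_only", "nuclear", 1, None, (1.0, 2.0, 3.0))


def test_impossible_density_raises_placement_error():
    with pytest.raises(PlacementError):
        pf.simulate_field(shape=(6, 48, 48), n_cells=1, n_signals=200, seed=0)


def test_snr_must_be_positive():
    with pytest.raises(ValueError):
        pf.simulate_field(snr=0.0, seed=0)
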