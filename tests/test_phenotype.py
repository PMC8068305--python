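"""Quantification, z-scoring, and multi-round clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from imctme import phenotype, synth
from imctme.stacks import ImageStack, LabelMask


def _toy_stack_and_mask():
    pixels = np.zeros((1, 4, 4))
    pixels[0, 0, :4] = [1.0, 2.0, 3.0, 4.0]
    labels = np.zeros((4, 4), dtype=np.int32)
    labels[0, :4] = 1
    return ImageStack(pixels=pixels, panel=[("m", "CD4")]), LabelMask(labels)


def test_quantify_single_cell_mean_and_area():
    stack, mask = _toy_stack_and_mask()
    table = phenotype.quantify_cells(mask, stack)
    assert len(table) == 1
    assert table.loc[0, "raw_CD4"] == pytest.approx(2.5)
    assert table.loc[0, "area_px"] == 4
    # unweighted centroid of (0, 0..3): x = 1.5, y = 0
    assert table.loc[0, "x_um"] == pytest.approx(1.5)
    assert table.loc[0, "y_um"] == pytest.approx(0.0)


def test_quantify_disjoint_cells_are_independent():
    pixels = np.zeros((1, 6, 6))
    labels = np.zeros((6, 6), dtype=np.int32)
    labels[0, 0:2] = 1
    labels[5, 4:6] = 2
    pixels[0, 0, 0:2] = 5.0
    pixels[0, 5, 4:6] = 7.0
    stack = ImageStack(pixels=pixels, panel=[("m", "CD4")])
    before = phenotype.quantify_cells(LabelMask(labels), stack)
    pixels2 = pixels.copy()
    pixels2[0, 0, 0:2] = 50.0  # perturb cell 1 only
    after = phenotype.quantify_cells(
        LabelMask(labels), ImageStack(pixels=pixels2, panel=[("m", "CD4")])
    )
    assert before.loc[1, "raw_CD4"] == after.loc[1, "raw_CD4"]
    assert before.loc[0, "raw_CD4"] != after.loc[0, "raw_CD4"]


def test_quantified_means_track_generating_profiles(rendered_tissue, cell_table):
    spec, _, _, truth = rendered_tissue
    merged = cell_table.merge(
        truth.cells[["cell_id", "subtype"]], on="cell_id", validate="one_to_one"
    )
    for subtype in ("tu_1", "CD8_4"):
        group = merged[merged["subtype"] == subtype]
        for marker in ("Keratin8_18", "CD8a"):
            expected = spec.subtype_profiles[subtype][marker][0]
            observed = group[f"raw_{marker}"].mean()
            assert observed == pytest.approx(expected, rel=0.25, abs=1.0)


def test_empty_mask_gives_empty_table():
    stack, _ = _toy_stack_and_mask()
    table = phenotype.quantify_cells(LabelMask(np.zeros((4, 4), dtype=np.int32)), stack)
    assert table.empty


def test_zscore_symmetric_pair_and_constant_marker():
    table = pd.DataFrame(
        {
            "sample_id": ["s", "s"],
            "cell_id": [1, 2],
            "raw_A": [0.0, 2.0],
            "raw_B": [5.0, 5.0],
        }
    )
    out = phenotype.zscore_normalize(table)
    np.testing.assert_allclose(out["z_A"], [-1.0, 1.0])  # population sd
    np.testing.assert_allclose(out["z_B"], [0.0, 0.0])


def test_zscore_invariant_to_row_order(cell_table):
    shuffled = cell_table.sample(frac=1.0, random_state=0)
    rezscored = phenotype.zscore_normalize(
        shuffled[[c for c in shuffled.columns if not c.startswith("z_")]]
    )
    merged = cell_table.merge(rezscored, on="cell_id", suffixes=("", "_shuf"))
    zcols = [c for c in cell_table.columns if c.startswith("z_")]
    for c in zcols:
        np.testing.assert_allclose(merged[c], merged[c + "_shuf"])


def _blob_table(n=500, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, 3)), rng.normal(sep, 1, (n // 2, 3))])
    return (
        pd.DataFrame(
            {
                "sample_id": "s",
                "cell_id": np.arange(n),
                "z_a": X[:, 0],
                "z_b": X[:, 1],
                "z_c": X[:, 2],
            }
        ),
        np.array([0] * (n // 2) + [1] * (n // 2)),
    )


def test_two_blobs_resolve_to_two_clusters():
    table, truth = _blob_table()
    labels = phenotype.cluster_round(table, ["a", "b", "c"], k=100, seed=0)
    assert labels.nunique() == 2
    agreement = max((labels == truth).mean(), (labels != truth).mean())
    assert agreement >= 0.99


def test_duplicated_points_co_cluster():
    table, _ = _blob_table(n=100)
    dup = pd.concat([table, table.assign(cell_id=table["cell_id"] + 1000)], ignore_index=True)
    labels = phenotype.cluster_round(dup, ["a", "b", "c"], k=20, seed=0)
    merged = pd.DataFrame({"cell_id": dup["cell_id"] % 1000, "label": labels})
    per_point = merged.groupby("cell_id")["label"].nunique()
    assert (per_point == 1).mean() >= 0.99


def test_clustering_is_deterministic_and_order_invariant():
    table, _ = _blob_table(n=200, seed=3)
    a = phenotype.cluster_round(table, ["a", "b", "c"], k=30, seed=5)
    b = phenotype.cluster_round(table, ["a", "b", "c"], k=30, seed=5)
    pd.testing.assert_series_equal(a, b)
    shuffled = table.sample(frac=1.0, random_state=1)
    c = phenotype.cluster_round(shuffled, ["a", "b", "c"], k=30, seed=5)
    joined = pd.DataFrame({"orig": a, "shuf": c.reindex(a.index)})
    # same partition up to label names
    assert adjusted_rand_score(joined["orig"], joined["shuf"]) == pytest.approx(1.0)


def test_cluster_round_requires_enough_cells():
    table, _ = _blob_table(n=20)
    with pytest.raises(ValueError, match="k\\+1"):
        phenotype.cluster_round(table, ["a", "b", "c"], k=30)


def test_single_round_protocol_equals_cluster_round():
    table, _ = _blob_table(n=200, seed=4)
    direct = phenotype.cluster_round(table, ["a", "b", "c"], k=30, seed=1)
    protocol = phenotype.ClusteringProtocol(
        rounds=[phenotype.ClusteringRound(markers=["a", "b", "c"], k=30)], seed=0
    )
    out = phenotype.run_protocol(table, protocol)
    assert adjusted_rand_score(direct, out["subtype_cluster"]) == pytest.approx(1.0)
    assert len(out) == len(table)  # row conservation


def test_multi_round_protocol_recovers_subtypes(rendered_tissue, cell_table):
    """Round 1 separates tumor/stroma; the pooled immune cells re-cluster in
    round 2 on immune markers.  Ground-truth recovery must be near-perfect
    on the well-separated default tissue."""
    _, _, _, truth = rendered_tissue
    protocol = phenotype.ClusteringProtocol(
        rounds=[
            phenotype.ClusteringRound(
                markers=["Keratin8_18", "SMA", "CD8a", "GranzymeB", "CD4", "CD45RO", "CD68", "CD73"],
                k=50,
                pool_rules=[
                    {"pool": "immune", "when": [["Keratin8_18", "<", 0.3], ["SMA", "<", 0.3]]}
                ],
            ),
            phenotype.ClusteringRound(
                markers=["CD8a", "GranzymeB", "CD4", "CD45RO", "CD68"], k=30, subset="immune"
            ),
        ],
        seed=0,
    )
    out = phenotype.run_protocol(cell_table, protocol)
    truth_sub = truth.cells.set_index("cell_id").loc[out["cell_id"], "subtype"]
    assert adjusted_rand_score(truth_sub, out["subtype_cluster"]) >= 0.8


def test_empty_round_subset_warns_and_skips():
    table, _ = _blob_table(n=200)
    protocol = phenotype.ClusteringProtocol(
        rounds=[
            phenotype.ClusteringRound(markers=["a", "b", "c"], k=30),
            phenotype.ClusteringRound(markers=["a"], k=10, subset="never_made"),
        ]
    )
    with pytest.warns(UserWarning, match="never_made"):
        out = phenotype.run_protocol(table, protocol)
    assert len(out) == len(table)


def test_annotation_rules_precedence_and_totality(cell_table, rendered_tissue):
    _, _, _, truth = rendered_tissue
    protocol = phenotype.ClusteringProtocol(
        rounds=[phenotype.ClusteringRound(markers=["Keratin8_18", "SMA", "CD8a", "CD4", "CD68", "CD73"], k=50)],
        seed=0,
    )
    out = phenotype.run_protocol(cell_table, protocol)
    # first-match-wins: the tu_2 rule must precede the generic tumor rule
    rules = [
        {"name": "tu_2", "when": [["Keratin8_18", ">", 0.3], ["CD73", ">", 0.3]]},
        {"name": "tumor", "when": [["Keratin8_18", ">", 0.3]]},
        {"name": "other", "when": []},
    ]
    ann = phenotype.annotate_subtypes(out, rules)
    truth_sub = truth.cells.set_index("cell_id").loc[ann["cell_id"], "subtype"].to_numpy()
    assert (ann.loc[truth_sub == "tu_2", "subtype"] == "tu_2").mean() > 0.9
    assert (ann.loc[truth_sub == "tu_1", "subtype"] == "tumor").mean() > 0.9

    with pytest.raises(ValueError, match="matches no annotation rule"):
        phenotype.annotate_subtypes(out, [{"name": "x", "when": [["CD8a", ">", 99.0]]}])


def test_protocol_from_dict_round_trip():
    cfg = {
        "seed": 3,
        "rounds": [
            {
                "markers": ["a", "b"],
                "k": 10,
                "pool_rules": [{"pool": "p", "when": [["a", "<", 0.0]]}],
            },
            {"markers": ["b"], "k": 5, "subset": "p"},
        ],
    }
    protocol = phenotype.protocol_from_dict(cfg)
    assert protocol.seed == 3
    assert protocol.rounds[1].subset == "p"
    assert protocol.rounds[0].pool_rules[0]["when"] == [["a", "<", 0.0]]
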