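import numpy as np
import pandas as pd
import pytest

from clawmorph import (
    ClawConfiguration,
    LandmarkPartition,
    MetadataTable,
    make_claw,
    ClawParams,
    prune_tree,
    read_newick,
    read_tps,
    simulate_tree,
    species_means,
    write_tps,
)
from clawmorph.data import CURVE_SIZES, N_LANDMARKS
from clawmorph.errors import (
    MalformedRecordError,
    TPSParseError,
    TreeError,
    ValidationError,
)

from conftest import random_configuration


# ---------------------------------------------------------------------------
# ClawConfiguration / LandmarkPartition
# ---------------------------------------------------------------------------

def test_configuration_rejects_wrong_count():
    with pytest.raises(ValidationError, match="83"):
        ClawConfiguration(specimen_id="x", coords=np.zeros((82, 2)))


def test_configuration_rejects_nonfinite():
    coords = np.zeros((83, 2))
    coords[5, 0] = np.nan
    with pytest.raises(ValidationError, match="non-finite"):
        ClawConfiguration(specimen_id="x", coords=coords)


def test_partition_default_layout():
    part = LandmarkPartition.default()
    assert part.core_indices == frozenset({1, 2, 3, 4} | set(range(7, 38)))
    assert part.sheath_indices == frozenset({5, 6} | set(range(38, 84)))
    assert len(part.core_indices) + len(part.sheath_indices) == 83


def test_partition_rejects_overlap():
    with pytest.raises(ValidationError):
        LandmarkPartition(frozenset(range(1, 43)), frozenset(range(42, 84)))


def test_curve_sizes():
    assert CURVE_SIZES == {"SL1": 13, "SL2": 18, "SL3": 28, "SL4": 18}


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

def test_tps_roundtrip_single_record(tmp_path, rng):
    cfg = random_configuration(rng)
    path = tmp_path / "one.tps"
    write_tps([cfg], path)
    back = read_tps(path)
    assert len(back) == 1
    assert back[0].coords.shape == (83, 2)
    np.testing.assert_allclose(back[0].coords, cfg.coords, atol=1e-12)
    assert back[0].specimen_id == cfg.specimen_id


def test_tps_roundtrip_with_scale(tmp_path, rng):
    cfg = random_configuration(rng)
    cfg = ClawConfiguration(
        specimen_id="scaled", coords=cfg.coords, scale=0.037
    )
    path = tmp_path / "scaled.tps"
    write_tps([cfg], path)
    back = read_tps(path)
    np.testing.assert_allclose(back[0].coords, cfg.coords, rtol=1e-12)
    assert back[0].scale == pytest.approx(0.037)


def test_tps_write_two_records(tmp_path, rng):
    cfgs = [random_configuration(rng) for _ in range(2)]
    path = tmp_path / "two.tps"
    write_tps(cfgs, path)
    text = path.read_text()
    assert text.count("LM=83") == 2
    coord_lines = [
        l for l in text.splitlines() if l and "=" not in l
    ]
    assert len(coord_lines) == 2 * 83


def test_tps_write_empty(tmp_path):
    path = tmp_path / "empty.tps"
    write_tps([], path)
    assert path.read_text() == ""


def test_tps_write_deterministic(tmp_path, rng):
    cfgs = [random_configuration(rng) for _ in range(3)]
    p1, p2 = tmp_path / "a.tps", tmp_path / "b.tps"
    write_tps(cfgs, p1)
    write_tps(cfgs, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_tps_curve_dialect(tmp_path, rng):
    """LM=6 + CURVES=4 blocks flatten to canonical order."""
    cfg = random_configuration(rng)
    lines = ["LM=6"]
    for x, y in cfg.coords[:6]:
        lines.append(f"{x:.17g} {y:.17g}")
    lines.append("CURVES=4")
    offset = 6
    for name in ("SL1", "SL2", "SL3", "SL4"):
        k = CURVE_SIZES[name]
        lines.append(f"POINTS={k}")
        for x, y in cfg.coords[offset:offset + k]:
            lines.append(f"{x:.17g} {y:.17g}")
        offset += k
    lines.append("ID=dialect_b")
    path = tmp_path / "curves.tps"
    path.write_text("\n".join(lines) + "\n")
    back = read_tps(path)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].coords, cfg.coords, atol=1e-12)
    assert back[0].specimen_id == "dialect_b"


def test_tps_wrong_count_is_malformed(tmp_path):
    body = "LM=82\n" + "\n".join("0.0 0.0" for _ in range(82)) + "\nID=x\n"
    path = tmp_path / "bad.tps"
    path.write_text(body)
    with pytest.raises(MalformedRecordError, match="LM=82"):
        read_tps(path)


def test_tps_nonnumeric_coordinate_names_line(tmp_path):
    lines = ["LM=83"] + ["0.0 0.0"] * 40 + ["oops zero"] + ["0.0 0.0"] * 42
    path = tmp_path / "bad2.tps"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(TPSParseError, match="line 42"):
        read_tps(path)


def test_tps_image_used_as_id(tmp_path, rng):
    cfg = random_configuration(rng)
    body = "LM=83\n" + "\n".join(
        f"{x:.17g} {y:.17g}" for x, y in cfg.coords
    ) + "\nIMAGE=radiograph_7.jpg\n"
    path = tmp_path / "img.tps"
    path.write_text(body)
    assert read_tps(path)[0].specimen_id == "radiograph_7.jpg"


# ---------------------------------------------------------------------------
# Newick and pruning
# ---------------------------------------------------------------------------

def test_read_newick_depths():
    tree = read_newick("((A:1,B:1):1,C:2);")
    assert sorted(tree.tips) == ["A", "B", "C"]
    depths = tree.tip_depths()
    assert all(abs(d - 2.0) < 1e-12 for d in depths.values())


def test_read_newick_duplicate_tip():
    with pytest.raises(TreeError, match="duplicate"):
        read_newick("((A:1,A:1):1,C:2);")


def test_read_newick_missing_branch_length():
    with pytest.raises(TreeError, match="branch length"):
        read_newick("((A:1,B):1,C:2);")


def test_newick_roundtrip_64_tips(tmp_path):
    tree = simulate_tree(64, seed=5)
    path = tmp_path / "t.nwk"
    tree.write_newick(path)
    back = read_newick(path)
    assert sorted(back.tips) == sorted(tree.tips)
    C1, order = tree.covariance()
    C2, _ = back.covariance(order)
    np.testing.assert_allclose(C1, C2, atol=1e-9)


def test_prune_identity():
    tree = read_newick("((A:1,B:1):1,C:2);")
    pruned = prune_tree(tree, ["A", "B", "C"])
    C1, order = tree.covariance()
    C2, _ = pruned.covariance(order)
    np.testing.assert_allclose(C1, C2, atol=1e-12)


def test_prune_sums_branch_lengths():
    # hand bookkeeping: removing B leaves A with path 1+1=2, C with 2
    tree = read_newick("((A:1,B:1):1,C:2);")
    pruned = prune_tree(tree, ["A", "C"])
    depths = pruned.tip_depths()
    assert depths["A"] == pytest.approx(2.0, abs=1e-12)
    assert depths["C"] == pytest.approx(2.0, abs=1e-12)
    C, order = pruned.covariance(["A", "C"])
    assert C[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_prune_empty_errors():
    tree = read_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(TreeError, match="empty"):
        prune_tree(tree, [])


def test_prune_unknown_species_listed():
    tree = read_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(TreeError, match="Zebra"):
        prune_tree(tree, ["A", "Zebra"])


def test_prune_preserves_covariance_submatrix():
    tree = simulate_tree(20, seed=9)
    keep = sorted(tree.tips)[:11]
    C_full, order = tree.covariance(keep)
    pruned = prune_tree(tree, keep)
    C_sub, _ = pruned.covariance(keep)
    np.testing.assert_allclose(C_full, C_sub, atol=1e-9)


# ---------------------------------------------------------------------------
# Metadata and species means
# ---------------------------------------------------------------------------

def _meta(rows):
    return MetadataTable(pd.DataFrame(rows))


def test_metadata_duplicate_specimen():
    with pytest.raises(ValidationError, match="duplicate"):
        _meta(
            [
                {"specimen_id": "s1", "species": "A", "ecology": "flying"},
                {"specimen_id": "s1", "species": "A", "ecology": "flying"},
            ]
        )


def test_species_means_single_specimen():
    meta = _meta([{"specimen_id": "s1", "species": "A", "ecology": "ground"}])
    vals = pd.DataFrame({"specimen_id": ["s1"], "m": [70.0]})
    out = species_means(vals, meta)
    assert out.loc["A", "m"] == 70.0
    assert out.loc["A", "ecology"] == "ground"


def test_species_means_arithmetic():
    meta = _meta(
        [
            {"specimen_id": "s1", "species": "A", "ecology": "ground"},
            {"specimen_id": "s2", "species": "A", "ecology": "ground"},
        ]
    )
    vals = pd.DataFrame({"specimen_id": ["s1", "s2"], "m": [70.0, 80.0]})
    assert species_means(vals, meta).loc["A", "m"] == 75.0


def test_species_means_matches_brute_force(rng):
    ids = [f"s{i}" for i in range(12)]
    spp = ["A", "B", "C"] * 4
    meta = _meta(
        [
            {"specimen_id": i, "species": s, "ecology": "flying"}
            for i, s in zip(ids, spp)
        ]
    )
    X = rng.normal(size=(12, 7))
    out = species_means(X, meta, specimen_ids=ids)
    for sp in "ABC":
        rows = [i for i, s in enumerate(spp) if s == sp]
        np.testing.assert_allclose(
            out.loc[sp].drop("ecology").to_numpy(float),
            X[rows].mean(axis=0),
            atol=1e-12,
        )


def test_species_means_permutation_invariant(rng):
    ids = [f"s{i}" for i in range(8)]
    spp = ["A"] * 4 + ["B"] * 4
    meta = _meta(
        [
            {"specimen_id": i, "species": s, "ecology": "flying"}
            for i, s in zip(ids, spp)
        ]
    )
    X = rng.normal(size=(8, 3))
    out1 = species_means(X, meta, specimen_ids=ids)
    perm = rng.permutation(8)
    out2 = species_means(X[perm], meta, specimen_ids=[ids[i] for i in perm])
    pd.testing.assert_frame_equal(out1, out2)


def test_species_means_log_after_averaging():
    meta = _meta(
        [
            {"specimen_id": "s1", "species": "A", "ecology": "ground"},
            {"specimen_id": "s2", "species": "A", "ecology": "ground"},
        ]
    )
    vals = pd.DataFrame({"specimen_id": ["s1", "s2"], "centroid_size": [10.0, 20.0]})
    out = species_means(vals, meta, log_columns=["centroid_size"])
    assert out.loc["A", "centroid_size"] == pytest.approx(np.log(15.0))


def test_species_means_conflicting_ecology():
    meta = _meta(
        [
            {"specimen_id": "s1", "species": "A", "ecology": "ground"},
            {"specimen_id": "s2", "species": "A", "ecology": "flying"},
        ]
    )
    vals = pd.DataFrame({"specimen_id": ["s1", "s2"], "m": [1.0, 2.0]})
    with pytest.raises(ValidationError, match="conflicting"):
        species_means(vals, meta)
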