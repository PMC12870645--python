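import numpy as np
import pandas as pd
import pytest

from lymphoniche.follicles import (
    FollicleConfig,
    Region,
    analyze_follicles,
    classify_follicle,
    detect_niche_regions,
    follicle_cluster_enrichment,
    mz_fraction_around_gc,
    mz_fraction_of_follicle,
    perifollicular_composition,
)
from lymphoniche.io_formats import StudyDesign
from lymphoniche.synthetic_data import TissueSimParams, generate_tissue
from tests.conftest import make_cells

CFG = FollicleConfig(
    gc_niche_set={"GC"}, mz_niche_set={"MZ"}, follicle_niche_set={"GC", "MZ"}
)


def niche_cells(xy, niches, **kw):
    cells = make_cells(xy, ["c"] * len(xy), **kw)
    cells["niche"] = list(niches)
    return cells


def disc_points(center, r, n, rng):
    u = rng.uniform(size=n)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    rad = r * np.sqrt(u)
    return np.column_stack(
        [center[0] + rad * np.cos(theta), center[1] + rad * np.sin(theta)]
    )


class TestDetectRegions:
    def test_no_target_cells_no_regions(self):
        cells = niche_cells([(0, 0), (5, 5)], ["other", "other"])
        assert detect_niche_regions(cells, {"GC"}, CFG) == []

    def test_three_separated_discs_recovered_exactly(self, rng):
        centers = [(100, 100), (400, 100), (250, 400)]
        parts, truth = [], []
        for c in centers:
            parts.append(disc_points(c, 40, 60, rng))
            truth.append(set())
        xy = np.concatenate(parts)
        cells = niche_cells(xy, ["GC"] * len(xy))
        for i, c in enumerate(centers):
            truth[i] = set(
                cells.loc[
                    np.hypot(cells["x_um"] - c[0], cells["y_um"] - c[1]) <= 40, "cell_id"
                ]
            )
        regions = detect_niche_regions(cells, {"GC"}, CFG)
        assert len(regions) == 3
        got = [set(r.member_ids) for r in regions]
        assert sorted(map(frozenset, got)) == sorted(map(frozenset, truth))

    def test_small_clump_below_min_size_discarded(self):
        cells = niche_cells([(i, 0) for i in range(5)], ["GC"] * 5)
        assert detect_niche_regions(cells, {"GC"}, CFG) == []  # min_region_cells=20

    def test_translation_and_permutation_invariance(self, rng):
        xy = disc_points((200, 200), 50, 80, rng)
        cells = niche_cells(xy, ["GC"] * 80)
        base = detect_niche_regions(cells, {"GC"}, CFG)
        shifted = cells.copy()
        shifted["x_um"] += 1234.5
        shifted["y_um"] -= 77.25
        moved = detect_niche_regions(shifted, {"GC"}, CFG)
        assert [set(r.member_ids) for r in base] == [set(r.member_ids) for r in moved]
        perm = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        permuted = detect_niche_regions(perm, {"GC"}, CFG)
        assert {frozenset(r.member_ids) for r in base} == {
            frozenset(r.member_ids) for r in permuted
        }


class TestMzFractions:
    def test_all_surrounding_cells_mz(self, rng):
        gc_xy = disc_points((0, 0), 10, 30, rng)
        ring = [(15, 0), (0, 15), (-15, 0), (0, -15)]
        xy = np.concatenate([gc_xy, ring])
        cells = niche_cells(xy, ["GC"] * 30 + ["MZ"] * 4)
        region = Region("r", "roi1", "GC", cells["cell_id"].to_numpy()[:30])
        frac, info = mz_fraction_around_gc(cells, region, CFG)
        assert frac == 1.0 and info["n_near"] == 4

    def test_no_mz_within_radius_zero(self, rng):
        gc_xy = disc_points((0, 0), 10, 30, rng)
        xy = np.concatenate([gc_xy, [(15, 0)], [(500, 500)]])
        cells = niche_cells(xy, ["GC"] * 30 + ["other", "MZ"])
        region = Region("r", "roi1", "GC", cells["cell_id"].to_numpy()[:30])
        frac, _ = mz_fraction_around_gc(cells, region, CFG)
        assert frac == 0.0

    def test_empty_neighborhood_flagged(self):
        cells = niche_cells([(0, 0), (500, 500)], ["GC", "MZ"])
        region = Region("r", "roi1", "GC", np.array([1]))
        frac, info = mz_fraction_around_gc(cells, region, CFG)
        assert frac == 0.0 and info["empty_neighborhood"]

    def test_annulus_against_brute_force_oracle(self, rng):
        gc_xy = disc_points((0, 0), 60, 120, rng)
        mz_xy = []
        while len(mz_xy) < 80:
            p = rng.uniform(-110, 110, size=2)
            if 60 <= np.hypot(*p) <= 100:
                mz_xy.append(p)
        other_xy = rng.uniform(-110, 110, size=(60, 2))
        xy = np.concatenate([gc_xy, np.array(mz_xy), other_xy])
        niches = ["GC"] * 120 + ["MZ"] * 80 + ["other"] * 60
        cells = niche_cells(xy, niches)
        gc_ids = cells["cell_id"].to_numpy()[:120]
        region = Region("r", "roi1", "GC", gc_ids)
        frac, info = mz_fraction_around_gc(cells, region, CFG)
        # brute force: per-cell min distance to any GC cell
        num = den = 0
        for i in range(len(cells)):
            if i < 120:
                continue
            d = np.min(np.hypot(xy[i, 0] - gc_xy[:, 0], xy[i, 1] - gc_xy[:, 1]))
            if d <= 20.0:
                den += 1
                if niches[i] == "MZ":
                    num += 1
        assert den == info["n_near"] and num == info["n_mz"]
        assert np.isclose(frac, num / den)

    def test_follicle_member_fraction_arithmetic(self, rng):
        xy = rng.uniform(0, 50, size=(100, 2))
        niches = ["GC"] * 60 + ["MZ"] * 40
        cells = niche_cells(xy, niches)
        region = Region("r", "roi1", "follicle", cells["cell_id"].to_numpy())
        assert mz_fraction_of_follicle(cells, region, CFG) == 0.4

    def test_all_mz_follicle_fraction_one(self):
        cells = niche_cells([(i, 0) for i in range(25)], ["MZ"] * 25)
        region = Region("r", "roi1", "follicle", cells["cell_id"].to_numpy())
        assert mz_fraction_of_follicle(cells, region, CFG) == 1.0


class TestClassification:
    def test_all_mz_region_dormant(self):
        region = Region("r", "roi1", "follicle", np.arange(30))
        assert classify_follicle(region, CFG, member_niches=["MZ"] * 30) == "dormant"

    def test_gc_core_without_mantle_decorticated(self):
        region = Region("r", "roi1", "follicle", np.arange(30), mz_fraction_around_gc=0.0)
        got = classify_follicle(region, CFG, member_niches=["GC"] * 30)
        assert got == "decorticated"

    def test_gc_core_with_mantle_active(self):
        region = Region("r", "roi1", "follicle", np.arange(30), mz_fraction_around_gc=0.9)
        got = classify_follicle(region, CFG, member_niches=["GC"] * 20 + ["MZ"] * 10)
        assert got == "active"


class TestSyntheticMaps:
    """Follicle analysis on generator output with true compartments as niches."""

    compartment_cfg = FollicleConfig(
        gc_niche_set={"GC-B"},
        mz_niche_set={"mantle-B"},
        follicle_niche_set={"GC-B", "mantle-B"},
    )

    def test_planted_follicles_recovered_and_nested(self):
        params = TissueSimParams(decortication_level=0.0)
        cells, truth = generate_tissue(params, seed=5)
        gcs, fols = analyze_follicles(
            cells, self.compartment_cfg, niche_labels=cells["compartment"]
        )
        assert len(fols) == len(truth.follicles) == len(gcs)
        # every GC nests inside exactly one follicle
        for gc in gcs:
            containing = [
                f for f in fols if set(gc.member_ids) <= set(f.member_ids)
            ]
            assert len(containing) == 1

    def test_intact_vs_decorticated_separation(self):
        intact_cells, _ = generate_tissue(TissueSimParams(decortication_level=0.0), seed=6)
        deco_cells, _ = generate_tissue(TissueSimParams(decortication_level=1.0), seed=7)
        _, intact = analyze_follicles(
            intact_cells, self.compartment_cfg, niche_labels=intact_cells["compartment"]
        )
        _, deco = analyze_follicles(
            deco_cells, self.compartment_cfg, niche_labels=deco_cells["compartment"]
        )
        lo = min(f.mz_fraction_around_gc for f in intact)
        hi = max(f.mz_fraction_around_gc for f in deco)
        assert lo > self.compartment_cfg.decortication_threshold > hi
        assert {f.follicle_class for f in intact} == {"active"}
        assert {f.follicle_class for f in deco} == {"decorticated"}

    def test_dormant_follicle_detected(self):
        params = TissueSimParams(n_follicles=2, follicle_kinds=["secondary", "primary"])
        cells, truth = generate_tissue(params, seed=8)
        _, fols = analyze_follicles(
            cells, self.compartment_cfg, niche_labels=cells["compartment"]
        )
        assert sorted(f.follicle_class for f in fols) == ["active", "dormant"]


class TestPerifollicular:
    def test_planted_ring_proportion(self, rng):
        fol_xy = disc_points((0, 0), 40, 60, rng)
        ring = []
        while len(ring) < 50:
            p = rng.uniform(-150, 150, size=2)
            if 45 <= np.hypot(*p) <= 130:
                ring.append(p)
        niches = ["GC"] * 60 + ["n28"] * 30 + ["other"] * 20
        xy = np.concatenate([fol_xy, np.array(ring)])
        cells = niche_cells(xy, niches)
        region = Region("r", "roi1", "follicle", cells["cell_id"].to_numpy()[:60])
        comp = perifollicular_composition(cells, [region], CFG)
        assert np.isclose(comp["proportion"].sum(), 1.0)
        got = comp.set_index("niche")["proportion"]
        assert np.isclose(got["n28"], 30 / 50)

    def test_requires_regions(self):
        cells = niche_cells([(0, 0)], ["GC"])
        with pytest.raises(ValueError):
            perifollicular_composition(cells, [], CFG)


class TestFollicleEnrichment:
    def test_absent_cluster_tests_at_p_one(self, rng):
        designs, cells_by_roi, regions_by_roi = [], {}, {}
        for i in range(6):
            roi = f"r{i}"
            ln = f"LN{i}"
            xy = disc_points((100, 100), 40, 60, rng)
            cells = make_cells(xy, rng.choice(["A", "B"], 60), roi_id=roi)
            cells["niche"] = "GC"
            cells.loc[0, "cluster"] = "A"
            cells_by_roi[roi] = cells
            regions_by_roi[roi] = [
                Region(f"{roi}:f", roi, "follicle", cells["cell_id"].to_numpy())
            ]
            designs.append(
                StudyDesign(ln, f"P{i}", "N1" if i < 3 else "N2",
                            "higher" if i < 3 else "lower", [roi])
            )
        # add a vocabulary-only cluster that never occurs inside follicles
        cells_by_roi["r0"] = pd.concat(
            [cells_by_roi["r0"],
             make_cells([(900, 900)], ["GHOST"], roi_id="r0", cell_ids=[9999])],
            ignore_index=True,
        )
        groups = {d.ln_id: "higher_N1" if d.station == "N1" else "rest" for d in designs}
        out = follicle_cluster_enrichment(
            cells_by_roi, regions_by_roi, designs, groups
        )
        ghost = out.loc[out["metric"] == "GHOST"].iloc[0]
        assert ghost["wilcoxon_p"] == 1.0
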