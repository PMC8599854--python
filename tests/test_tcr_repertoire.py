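import numpy as np
import pandas as pd
import pytest

from ithseq.io_cohort import ClonotypeTable
from ithseq.synthetic_cohort import SimulationConfig, simulate_repertoire
from ithseq.tcr_repertoire import (
    overlap_metrics, repertoire_metrics, sharing_classes, tumor_vs_adjacent_contrast,
)


def table(freqs, templates=None, region="R1", cells=1000):
    n = len(freqs)
    names = [f"clone{i:03d}" for i in range(n)]
    t = templates if templates is not None else [max(1, int(f * 1000)) for f in freqs]
    rows = pd.DataFrame({
        "rearrangement": names, "templates": t, "productive_frequency": list(freqs)})
    return ClonotypeTable("P", region, rows, int(sum(t)), cells)


def named_table(counts: dict, region="R1", cells=1000):
    rows = pd.DataFrame({
        "rearrangement": list(counts), "templates": list(counts.values()),
        "productive_frequency": np.array(list(counts.values())) / sum(counts.values()),
    })
    return ClonotypeTable("P", region, rows, sum(counts.values()), cells)


class TestMetrics:
    def test_even_two_clone_repertoire_has_zero_clonality(self):
        m = repertoire_metrics(table([0.5, 0.5]))
        assert m.clonality == 0.0

    def test_skewed_two_clone_entropy_value(self):
        # H(0.9, 0.1) = 0.325083, clonality = 1 - H/ln2 = 0.531004
        m = repertoire_metrics(table([0.9, 0.1]))
        assert m.clonality == pytest.approx(0.531004, abs=1e-6)

    def test_density_is_templates_per_cell(self):
        m = repertoire_metrics(table([1.0], templates=[100], cells=1000))
        assert m.density == pytest.approx(0.1)

    def test_single_clone_clonality_defined_zero(self):
        assert repertoire_metrics(table([1.0])).clonality == 0.0

    def test_zero_input_cells_gives_missing_density(self):
        m = repertoire_metrics(table([0.5, 0.5], cells=0))
        assert np.isnan(m.density) and m.richness == 2

    def test_clonality_invariant_to_template_scaling(self):
        a = named_table({"x": 10, "y": 30, "z": 60})
        b = named_table({"x": 100, "y": 300, "z": 600})
        ma, mb = repertoire_metrics(a), repertoire_metrics(b)
        assert ma.clonality == pytest.approx(mb.clonality)


class TestOverlap:
    def test_identical_tables_all_ones(self):
        a = named_table({"x": 10, "y": 20})
        om = overlap_metrics(a, a)
        assert om.jaccard == 1.0 and om.top20_shared == 1.0
        assert om.morisita == pytest.approx(1.0)

    def test_disjoint_tables_all_zero(self):
        a = named_table({"x": 10, "y": 20})
        b = named_table({"u": 10, "v": 20})
        om = overlap_metrics(a, b)
        assert (om.jaccard, om.morisita, om.top20_shared) == (0.0, 0.0, 0.0)

    def test_hand_computed_values(self):
        a = named_table({"x": 10, "y": 10})
        b = named_table({"y": 10, "z": 10})
        om = overlap_metrics(a, b)
        assert om.jaccard == pytest.approx(1 / 3)
        assert om.morisita == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = named_table({f"c{i}": int(rng.integers(1, 50)) for i in range(30)})
        b = named_table({f"c{i}": int(rng.integers(1, 50)) for i in range(10, 40)})
        ab, ba = overlap_metrics(a, b), overlap_metrics(b, a)
        assert ab.jaccard == ba.jaccard
        assert ab.morisita == pytest.approx(ba.morisita)
        assert ab.top20_shared == ba.top20_shared

    def test_morisita_scale_invariance(self):
        a = named_table({"x": 10, "y": 20})
        b = named_table({"x": 5, "y": 1, "z": 4})
        b10 = named_table({"x": 50, "y": 10, "z": 40})
        assert overlap_metrics(a, b).morisita == pytest.approx(
            overlap_metrics(a, b10).morisita)


class TestSharing:
    def test_fully_shared(self):
        t = named_table({"x": 5, "y": 5})
        props = sharing_classes([t, named_table({"x": 5, "y": 5}, region="R2")])
        assert props == {"shared": 1.0, "intermediate": 0.0, "private": 1.0 - 1.0}

    def test_fully_private(self):
        a = named_table({"x": 5})
        b = named_table({"u": 5}, region="R2")
        props = sharing_classes([a, b])
        assert props["private"] == 1.0 and props["shared"] == 0.0

    def test_counting_three_regions(self):
        # 1 ubiquitous, 19 in two regions, 80 private -> (0.01, 0.19, 0.80)
        ubiq = {"u0": 1}
        two = {f"t{i}": 1 for i in range(19)}
        priv = [{f"p{r}_{i}": 1 for i in range(27 if r == 0 else 27 if r == 1 else 26)}
                for r in range(3)]
        t1 = named_table({**ubiq, **two, **priv[0]}, region="R1")
        t2 = named_table({**ubiq, **two, **priv[1]}, region="R2")
        t3 = named_table({**ubiq, **priv[2]}, region="R3")
        props = sharing_classes([t1, t2, t3])
        assert props["shared"] == pytest.approx(0.01)
        assert props["intermediate"] == pytest.approx(0.19)
        assert props["private"] == pytest.approx(0.80)

    def test_single_region_errors(self):
        with pytest.raises(ValueError):
            sharing_classes([named_table({"x": 1})])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        tables = [named_table({f"c{rng.integers(0, 60)}": 1 + i for i in range(20)},
                              region=f"R{j}") for j in range(3)]
        props = sharing_classes(tables)
        assert sum(props.values()) == pytest.approx(1.0)


class TestSubsampling:
    def test_downsampling_never_increases_richness(self):
        rng = np.random.default_rng(7)
        counts = {f"c{i}": int(rng.integers(1, 40)) for i in range(50)}
        t = named_table(counts)
        full = repertoire_metrics(t).richness
        pool = np.repeat(t.rows["rearrangement"].values, t.rows["templates"].values)
        for _ in range(50):
            sub = rng.choice(pool, size=len(pool) // 2, replace=False)
            vals, cnt = np.unique(sub, return_counts=True)
            sub_t = named_table(dict(zip(vals, cnt)))
            assert repertoire_metrics(sub_t).richness <= full


class TestTumorVsAdjacent:
    def _frames(self, shift, n=16, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(np.log(0.02), 0.4, n)
        tumor = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                              "density": base * shift,
                              "richness": rng.integers(100, 1000, n).astype(float),
                              "clonality": rng.uniform(0.005, 0.05, n)})
        adj = tumor.copy()
        adj["density"] = base
        return tumor, adj

    def test_identical_groups_near_null(self):
        tumor, _ = self._frames(1.0)
        res = tumor_vs_adjacent_contrast(tumor, tumor.copy())
        assert (res["p_value"] > 0.9).all()

    def test_shifted_density_detected_in_most_replicates(self):
        hits = 0
        for seed in range(40):
            tumor, adj = self._frames(0.2, seed=seed)
            res = tumor_vs_adjacent_contrast(tumor, adj).set_index("metric")
            hits += res.loc["density", "p_value"] < 0.05
        assert hits >= 36  # >= 90%

    def test_two_pairs_errors(self):
        tumor, adj = self._frames(1.0, n=2)
        with pytest.raises(ValueError):
            tumor_vs_adjacent_contrast(tumor, adj)


class TestSimulatedRepertoires:
    def test_full_sharing_gives_jaccard_one(self):
        cfg = SimulationConfig(shared_clone_fraction=1.0, repertoire_size=50,
                               total_templates=500)
        rng = np.random.default_rng(0)
        pool = [f"pool{i}" for i in range(50)]
        a = simulate_repertoire(cfg, pool, "P", "R1", rng)
        b = simulate_repertoire(cfg, pool, "P", "R2", rng)
        assert overlap_metrics(a, b).jaccard == 1.0

    def test_no_sharing_gives_jaccard_zero(self):
        cfg = SimulationConfig(shared_clone_fraction=0.0, repertoire_size=50,
                               total_templates=500)
        rng = np.random.default_rng(0)
        a = simulate_repertoire(cfg, [], "P", "R1", rng)
        b = simulate_repertoire(cfg, [], "P", "R2", rng)
        assert overlap_metrics(a, b).jaccard == 0.0

    def test_heavy_tail_has_higher_clonality_at_matched_richness(self):
        cfg = SimulationConfig(repertoire_size=300, total_templates=3000)
        rng = np.random.default_rng(2)
        heavy = simulate_repertoire(cfg, [], "P", "R1", rng, alpha=0.8)
        even = simulate_repertoire(cfg, [], "P", "R2", rng, alpha=8.0)
        assert (repertoire_metrics(heavy).clonality
                > repertoire_metrics(even).clonality)

    def test_invalid_alpha_errors(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            simulate_repertoire(cfg, [], "P", "R1", np.random.default_rng(0), alpha=0.0)
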