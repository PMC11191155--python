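import numpy as np
import pandas as pd
import pytest

from consensig.core_types import CountMatrix, NormMatrix, SampleTable
from consensig.normalize import (
    FilterParams,
    apply_mask,
    filter_batch_inconsistent,
    filter_genes,
    log_cpm,
    tmm_factors,
)
from consensig.simulate import SimConfig, simulate_dataset


def brute_force_tmm(obs, ref, trim_m=0.30, trim_a=0.05):
    """Independent direct coding of the doubly trimmed weighted mean of M-values."""
    n_o, n_r = sum(obs), sum(ref)
    rows = [
        (np.log2((o / n_o) / (r / n_r)),
         0.5 * np.log2((o / n_o) * (r / n_r)),
         1.0 / ((n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)))
        for o, r in zip(obs, ref)
        if o > 0 and r > 0
    ]
    n = len(rows)
    ms = sorted(r[0] for r in rows)
    as_ = sorted(r[1] for r in rows)
    lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
    keep_m = set(ms[lo_m:hi_m])
    keep_a = set(as_[lo_a:hi_a])
    kept = [(m, a, w) for m, a, w in rows if m in keep_m and a in keep_a]
    num = sum(w * m for m, _, w in kept)
    den = sum(w for _, _, w in kept)
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        v = np.tile(np.arange(1, 31)[:, None], (1, 3))
        cm = CountMatrix([f"g{i}" for i in range(30)], ["a", "b", "c"], v)
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_scaling_cancels(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 1000, 40)
        cm = CountMatrix([f"g{i}" for i in range(40)], ["a", "b"],
                         np.column_stack([col, 2 * col]))
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_composition_example_matches_brute_force(self):
        """Sample B doubles genes 1-15 only; factor must match the direct formula.

        60 genes, so the double trim leaves enough usable genes (a 20-gene
        toy falls below the 10-gene floor and triggers the unit-factor
        fallback instead).
        """
        rng = np.random.default_rng(7)
        a = rng.integers(50, 500, 60)
        b = a.copy()
        b[:15] *= 2
        cm = CountMatrix([f"g{i}" for i in range(60)], ["A", "B"], np.column_stack([a, b]))
        nf = tmm_factors(cm)
        ref = nf.reference_sample
        obs = "B" if ref == "A" else "A"
        cols = {"A": a, "B": b}
        expected = brute_force_tmm(cols[obs].tolist(), cols[ref].tolist())
        got = nf.factors[cm.sample_ids.index(obs)] / nf.factors[cm.sample_ids.index(ref)]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_geometric_mean_is_one(self, small_counts):
        nf = tmm_factors(small_counts)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_errors(self):
        v = np.ones((5, 2), int)
        v[:, 1] = 0
        cm = CountMatrix([f"g{i}" for i in range(5)], ["a", "b"], v)
        with pytest.raises(ValueError, match="no counts"):
            tmm_factors(cm)

    def test_sample_order_invariance(self, small_counts):
        nf = tmm_factors(small_counts)
        perm = [2, 0, 3, 1]
        cm2 = CountMatrix(
            small_counts.gene_ids,
            [small_counts.sample_ids[j] for j in perm],
            small_counts.values[:, perm],
        )
        nf2 = tmm_factors(cm2)
        lookup = dict(zip(nf2.sample_ids, nf2.factors))
        assert np.allclose([lookup[s] for s in nf.sample_ids], nf.factors)

    def test_matches_edger(self, tmp_path):
        """Cross-check against the standard R implementation on a toy matrix."""
        import shutil
        import subprocess

        rng = np.random.default_rng(42)
        v = rng.negative_binomial(5, 0.01, size=(200, 4))
        v[:50, 1] *= 3  # composition shift in sample 2
        cm = CountMatrix([f"g{i}" for i in range(200)], ["s1", "s2", "s3", "s4"], v)
        nf = tmm_factors(cm)
        np.savetxt(tmp_path / "m.txt", v, fmt="%d")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR));'
            'm <- as.matrix(read.table("%s"));'
            'f <- calcNormFactors(m, method="TMM");'
            'cat(f, sep="\\n")' % (tmp_path / "m.txt")
        )
        out = subprocess.run(
            [shutil.which("Rscript"), str(script)], capture_output=True, text=True, check=True
        )
        r_factors = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(nf.factors, r_factors, rtol=2e-2)


class TestLogCpm:
    def test_zero_count_closed_form(self):
        # construct library size 1e6 in both samples
        v = np.zeros((2, 2), int)
        v[1] = 10**6
        cm = CountMatrix(["a", "b"], ["s", "t"], v)
        nf = tmm_factors(cm)
        nm = log_cpm(cm, nf, prior_count=0.5)
        expected = np.log2(0.5 / (10**6 + 1) * 10**6)
        assert nm.values[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_known_count_closed_form(self):
        v = np.array([[1000, 1000], [10**6 - 1000, 10**6 - 1000]])
        cm = CountMatrix(["a", "b"], ["s", "t"], v)
        nf = tmm_factors(cm)
        nm = log_cpm(cm, nf, prior_count=0.5)
        assert nm.values[0, 0] == pytest.approx(np.log2(1000.5 / (10**6 + 1) * 10**6), abs=1e-9)
        assert nm.values[0, 0] == pytest.approx(9.966, abs=1e-3)

    def test_depth_invariance_for_large_counts(self):
        rng = np.random.default_rng(1)
        col = rng.integers(100, 5000, 50)
        cm1 = CountMatrix([f"g{i}" for i in range(50)], ["a", "b"], np.column_stack([col, col]))
        cm2 = CountMatrix([f"g{i}" for i in range(50)], ["a", "b"], np.column_stack([2 * col, 2 * col]))
        nm1 = log_cpm(cm1, tmm_factors(cm1))
        nm2 = log_cpm(cm2, tmm_factors(cm2))
        assert np.max(np.abs(nm1.values - nm2.values)) < 0.01

    def test_misaligned_factors_error(self, small_counts):
        nf = tmm_factors(small_counts)
        nf.sample_ids = list(reversed(nf.sample_ids))
        with pytest.raises(ValueError, match="aligned"):
            log_cpm(small_counts, nf)


def _norm_matrix(values, samples=None, roles=None, classes=None, batches=None):
    n_g, n_s = values.shape
    gene_ids = [f"g{i}" for i in range(n_g)]
    sample_ids = samples or [f"s{j}" for j in range(n_s)]
    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "class_label": classes if classes is not None else [0, 1] * (n_s // 2),
                "batch_id": batches if batches is not None else ["b1"] * n_s,
                "role": roles if roles is not None else ["train"] * n_s,
            }
        )
    )
    return NormMatrix(gene_ids, sample_ids, values), st


class TestFilterGenes:
    def test_expression_rule_respects_quantile_boundary(self):
        rng = np.random.default_rng(0)
        base = np.linspace(1, 10, 100)[:, None]
        vals = np.repeat(base, 8, axis=1)
        vals[:, ::2] += 1.0  # class-0 columns higher: no gene fails the fc rule
        nm, st = _norm_matrix(vals)
        mask = filter_genes(nm, st, FilterParams(expr_quantile=0.05, min_abs_lfc=0.0))
        assert (~mask.kept).sum() <= 5

    def test_low_fc_removed_with_reason(self):
        vals = np.zeros((3, 6))
        vals[0, :] = [5.0, 5.05, 5.0, 5.05, 5.0, 5.05]   # |diff| = 0.05 -> removed
        vals[1, :] = [5.0, 5.10, 5.0, 5.10, 5.0, 5.10]   # exactly 0.1 -> kept
        vals[2, :] = [9.0, 5.0, 9.0, 5.0, 9.0, 5.0]
        nm, st = _norm_matrix(vals)
        mask = filter_genes(nm, st, FilterParams(expr_quantile=0.0, min_abs_lfc=0.1))
        assert not mask.kept[0] and mask.reason[0] == "low_fc"
        assert mask.kept[1]  # strict "<" boundary
        assert mask.kept[2]

    def test_single_class_train_errors(self):
        vals = np.random.default_rng(0).normal(size=(5, 4))
        nm, st = _norm_matrix(vals, classes=[0, 0, 0, 0])
        with pytest.raises(ValueError, match="both classes"):
            filter_genes(nm, st)

    def test_validation_samples_ignored(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, size=(40, 8))
        nm, st = _norm_matrix(vals, roles=["train"] * 4 + ["validation"] * 4)
        vals2 = vals.copy()
        vals2[:, 4:] = -100.0  # mangle validation columns only
        nm2 = NormMatrix(nm.gene_ids, nm.sample_ids, vals2)
        m1 = filter_genes(nm, st)
        m2 = filter_genes(nm2, st)
        assert m1.kept.tolist() == m2.kept.tolist()


class TestBatchConsistencyFilter:
    def test_same_sign_kept_flip_removed(self):
        # batches of 4 samples (2 per class); gene0 consistent, gene1 flips in b2
        vals = np.zeros((2, 12))
        diffs0 = {0: 0.4, 1: 0.2, 2: 0.3}
        diffs1 = {0: 0.4, 1: -0.2, 2: 0.3}
        for b in range(3):
            cols = slice(4 * b, 4 * b + 4)
            base = np.zeros(4)
            vals[0, cols] = [diffs0[b], 0, diffs0[b], 0]
            vals[1, cols] = [diffs1[b], 0, diffs1[b], 0]
        nm, st = _norm_matrix(
            vals, batches=[f"b{b}" for b in range(3) for _ in range(4)],
            classes=[0, 1, 0, 1] * 3,
        )
        mask = filter_batch_inconsistent(nm, st)
        assert mask.kept[0]
        assert not mask.kept[1] and mask.reason[1] == "batch_inconsistent"

    def test_single_batch_identity(self):
        vals = np.random.default_rng(0).normal(size=(6, 4))
        nm, st = _norm_matrix(vals)
        mask = filter_batch_inconsistent(nm, st)
        assert mask.kept.all()

    def test_batch_missing_class_errors(self):
        vals = np.random.default_rng(0).normal(size=(4, 6))
        nm, st = _norm_matrix(
            vals, batches=["b1"] * 4 + ["b2"] * 2, classes=[0, 1, 0, 1, 0, 0]
        )
        with pytest.raises(ValueError, match="missing a class"):
            filter_batch_inconsistent(nm, st)


class TestFilterProperties:
    def test_filters_commute_via_intersection(self, sim_two_batch):
        ds, _ = sim_two_batch
        nm = log_cpm(ds.matrix, tmm_factors(ds.matrix))
        m1 = filter_genes(nm, ds.samples)
        m2 = filter_batch_inconsistent(nm, ds.samples)
        a = m1.intersect(m2)
        b = m2.intersect(m1)
        assert a.kept.tolist() == b.kept.tolist()

    def test_planted_genes_survive_filters(self):
        """Strong planted signal passes both filters across seeds."""
        ok = 0
        for seed in range(10):
            cfg = SimConfig(
                n_genes=200, n_batches=2, samples_per_batch=40, n_signal=8,
                signal_lfc=2.0, batch_logfc_sd=0.0, seed=seed,
            )
            ds, truth = simulate_dataset(cfg)
            nm = log_cpm(ds.matrix, tmm_factors(ds.matrix))
            mask = filter_genes(nm, ds.samples).intersect(filter_batch_inconsistent(nm, ds.samples))
            kept = set(mask.kept_genes())
            ok += set(truth.signal_genes) <= kept
        assert ok >= 9  # >= 95% of seeds at full scale; 9/10 here

    def test_apply_mask_subsets(self, sim_two_batch):
        ds, _ = sim_two_batch
        nm = log_cpm(ds.matrix, tmm_factors(ds.matrix))
        mask = filter_genes(nm, ds.samples)
        sub = apply_mask(nm, mask)
        assert sub.n_genes == int(mask.kept.sum())
        assert sub.gene_ids == mask.kept_genes()
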