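"""Sire segregation tests: transmission labels, Z-score likelihood, calls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from qtnscan import segregation, simdata
from qtnscan.containers import SireFamily
from qtnscan.segregation import (analyze_sire, build_sire_family,
                                 classify_sire, concordance_test,
                                 infer_transmitted_haplotype, sire_zscore)


def _family(sire_haps, off_dos, dam_dos, phenos, pos=None):
    m = sire_haps.shape[1]
    return SireFamily(
        sire_id="sire", marker_ids=[f"m{j}" for j in range(m)],
        marker_pos=pos if pos is not None else (np.arange(m) + 1) * 1000,
        sire_haps=np.asarray(sire_haps, dtype=float),
        offspring_ids=[f"o{i}" for i in range(len(off_dos))],
        offspring_dosage=np.asarray(off_dos, dtype=float),
        dam_dosage=np.asarray(dam_dos, dtype=float),
        phenotypes=np.asarray(phenos, dtype=float),
    )


class TestTransmission:
    def test_forced_transmission_from_homozygous_dam(self):
        fam = _family(np.array([[1], [0]]), [[1.0]], [[0.0]], [0.0])
        labels = infer_transmitted_haplotype(fam, 1000)
        assert labels["o0"] == "hap1"

    def test_ambiguous_marker_falls_to_next_informative(self):
        # marker 0: sire 1|0, dam 1/0, offspring 1/0 -> ambiguous
        # marker 1 (further away): sire 1|0, dam 0/0, offspring 0/0 -> hap2
        fam = _family(np.array([[1, 1], [0, 0]]),
                      [[1.0, 0.0]], [[1.0, 0.0]], [0.0],
                      pos=np.array([1000, 5000]))
        labels = infer_transmitted_haplotype(fam, 1000)
        assert labels["o0"] == "hap2"

    def test_unresolvable_offspring_labeled_unknown(self):
        fam = _family(np.array([[1], [0]]), [[1.0]], [[1.0]], [0.0])
        assert infer_transmitted_haplotype(fam, 1000)["o0"] == "unknown"

    def test_sire_homozygous_everywhere_raises(self):
        fam = _family(np.array([[1, 0], [1, 0]]), [[1.0, 0.0]],
                      [[np.nan, np.nan]], [0.0])
        with pytest.raises(ValueError, match="homozygous"):
            infer_transmitted_haplotype(fam, 1000)

    def test_labels_match_simulator_truth(self, small_sim):
        """With phase known, nearest-marker labels recover the true gamete."""
        g = small_sim.genotypes
        ped = small_sim.pedigree
        ph = small_sim.phenotypes
        resid = pd.Series(ph["rg"].to_numpy(), index=ph.index)
        sire = "F1_b0"
        qtn_pos = small_sim.truth.qtn_pos_bp
        fam = build_sire_family(g, ped, resid, sire, small_sim.truth.qtn_chrom,
                                qtn_pos - 2_000_000, qtn_pos + 2_000_000)
        labels = infer_transmitted_haplotype(fam, qtn_pos)
        # truth: which paternal haplotype the offspring carries at the QTN
        jq = fam.marker_ids.index("qtn")
        srow = g.sample_indexer([sire])[0]
        cols = [g.snp_index(s) for s in fam.marker_ids]
        correct = total = 0
        for r, kid in enumerate(fam.offspring_ids):
            if labels[kid] == "unknown":
                continue
            krow = g.sample_indexer([kid])[0]
            pat_allele = g.haplotypes[krow, cols[jq], 0]  # first gamete = sire's
            sire_h = g.haplotypes[srow, cols[jq]]
            if sire_h[0] == sire_h[1]:
                continue  # QTN uninformative in this sire
            truth_label = "hap1" if pat_allele == sire_h[0] else "hap2"
            total += 1
            correct += labels[kid] == truth_label
        assert total > 20
        assert correct / total >= 0.95


def zscore_likelihood_oracle(y, labels):
    """Z from explicitly maximized normal likelihoods (common variance)."""
    y = np.asarray(y, dtype=float)
    lab = np.asarray(labels)
    keep = lab != "unknown"
    y, lab = y[keep], lab[keep]
    n = len(y)

    def max_loglik(means_by_class):
        mu = np.array([means_by_class[l] for l in lab])
        sigma2 = np.mean((y - mu) ** 2)  # ML variance
        return np.sum(stats.norm.logpdf(y, mu, np.sqrt(sigma2)))

    # H1: one mean per class (ML = class means); H0: grand mean
    m1 = {c: y[lab == c].mean() for c in ("hap1", "hap2")}
    m0 = {c: y.mean() for c in ("hap1", "hap2")}
    return (max_loglik(m1) - max_loglik(m0)) / math.log(10)


class TestZScore:
    def test_identical_class_sets_give_zero(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["hap1"] * 3 + ["hap2"] * 3
        assert sire_zscore(y, labels) == pytest.approx(0.0, abs=1e-12)

    def test_two_sd_separation_with_40_offspring_exceeds_threshold(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
        labels = ["hap1"] * 20 + ["hap2"] * 20
        assert sire_zscore(y, labels) > 2.0

    def test_equals_explicit_likelihood_maximization(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            n1, n2 = rng.integers(3, 15, size=2)
            y = np.concatenate([rng.normal(0, 1, n1),
                                rng.normal(rng.normal(), 1, n2)])
            labels = ["hap1"] * n1 + ["hap2"] * n2
            assert sire_zscore(y, labels) == pytest.approx(
                zscore_likelihood_oracle(y, labels), abs=1e-9)

    def test_invariant_to_label_swap_shift_and_scale(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        labels = np.array(["hap1"] * 15 + ["hap2"] * 15)
        z = sire_zscore(y, labels)
        swapped = np.where(labels == "hap1", "hap2", "hap1")
        assert sire_zscore(y, swapped) == pytest.approx(z)
        assert sire_zscore(y + 100.0, labels) == pytest.approx(z)
        assert sire_zscore(y * 7.0, labels) == pytest.approx(z)

    def test_class_with_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            sire_zscore([1.0, 2.0, 3.0], ["hap1", "hap1", "hap2"])


class TestClassify:
    @pytest.mark.parametrize("z,call", [
        (2.5, "Qq"), (-3.0, "homozygous"), (0.0, "undetermined"),
        (2.0, "undetermined"), (-2.0, "undetermined"),
    ])
    def test_published_thresholds(self, z, call):
        assert classify_sire(z) == call

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            classify_sire(float("nan"))


class TestConcordance:
    def _result(self, sire, call, high_hap=0):
        return segregation.SegregationResult(
            sire_id=sire, z=3.0 if call == "Qq" else -3.0, call=call,
            labels=pd.Series(dtype=object), high_hap=high_hap)

    def test_single_het_sire_is_concordant(self):
        res = [self._result("s1", "Qq")]
        assert concordance_test({"s1": 1}, res) == (1, 1, True)

    def test_undetermined_sires_excluded(self):
        res = [self._result("s1", "Qq"),
               segregation.SegregationResult("s2", 0.0, "undetermined",
                                             pd.Series(dtype=object))]
        n_conc, n_tested, fully = concordance_test({"s1": 1, "s2": 2}, res)
        assert (n_conc, n_tested, fully) == (1, 1, True)

    def test_orientation_conflict_breaks_full_concordance(self):
        res = [self._result("s1", "Qq"), self._result("s2", "Qq")]
        n_conc, n_tested, fully = concordance_test(
            {"s1": 1, "s2": 1}, res,
            candidate_high_allele={"s1": 1, "s2": 0})
        assert n_conc == 2 and n_tested == 2 and not fully

    def test_all_undetermined_raises(self):
        res = [segregation.SegregationResult("s1", 0.0, "undetermined",
                                             pd.Series(dtype=object))]
        with pytest.raises(ValueError):
            concordance_test({"s1": 1}, res)

    def test_causal_candidate_fully_concordant_on_simulation(self, default_sim):
        """Mirrors the all-sires concordance check on synthetic truth."""
        sim = default_sim
        g, ped, ph = sim.genotypes, sim.pedigree, sim.phenotypes
        resid = pd.Series(ph["rg"].to_numpy(), index=ph.index)
        qtn_pos = sim.truth.qtn_pos_bp
        results = []
        cand_geno, high_allele = {}, {}
        jq = g.snp_index("qtn")
        for sire in sorted(sim.truth.sire_qtl_genotype):
            try:
                fam = build_sire_family(
                    g, ped, resid, sire, sim.truth.qtn_chrom,
                    qtn_pos - 2_000_000, qtn_pos + 2_000_000)
                r = analyze_sire(fam, qtn_pos)
            except ValueError:
                continue
            results.append(r)
            srow = g.sample_indexer([sire])[0]
            cand_geno[r.sire_id] = int(g.dosage[srow, jq])
            if r.call == "Qq":
                high_allele[r.sire_id] = int(g.haplotypes[srow, jq, r.high_hap])
        n_conc, n_tested, fully = concordance_test(
            cand_geno, results, candidate_high_allele=high_allele)
        assert n_tested >= 8
        assert fully and n_conc == n_tested
        # unlinked candidate: het status is essentially random across sires
        far = [s for s in g.snp_ids if s.startswith("c3_")][10]
        jf = g.snp_index(far)
        alt_geno = {r.sire_id: int(g.dosage[g.sample_indexer([r.sire_id])[0], jf])
                    for r in results}
        n_alt, n_t_alt, fully_alt = concordance_test(alt_geno, results)
        assert n_alt <= n_t_alt  # sanity; full concordance is not expected
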