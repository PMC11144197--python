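"""Synthetic telomere arrays, WGS-like reads, and terminal reads."""

import collections

import numpy as np
import pytest
from scipy import stats

from telovar import (
    ModelParams,
    ReadSimParams,
    TerminalSimParams,
    forward_p_add,
    reverse_complement,
    simulate_telomere_array,
    simulate_terminal_reads,
    simulate_wgs_reads,
    spectrum,
    write_fastq,
)
from telovar.composition import RunLengthTable


class TestTelomereArray:
    def test_fully_processive_enzyme_never_switches(self):
        params = ModelParams(p_x_wt=1.0, p_x_var=1.0, rho=0.5, degeneracy=0.0)
        # find a seed whose first association is wild-type, then the whole
        # array must stay wild-type
        for seed in range(10):
            array = simulate_telomere_array(params, 500, seed=seed)
            if array.alleles[0] == "wt":
                break
        assert set(array.hexamers) == {"TTAGGG"}
        assert set(array.alleles) == {"wt"}

    def test_non_processive_enzyme_run_fractions(self):
        params = ModelParams(p_x_wt=0.0, p_x_var=0.0, rho=0.5, degeneracy=0.0)
        array = simulate_telomere_array(params, 100_000, seed=42)
        classes = array.unit_classes()
        var_frac = classes.count("var") / len(classes)
        assert var_frac == pytest.approx(0.5, abs=0.01)
        table = RunLengthTable.from_unit_classes(classes)
        counts = table.runs["var"]
        total = sum(counts.values())
        ge2 = sum(n for x, n in counts.items() if x >= 2) / total
        ge3 = sum(n for x, n in counts.items() if x >= 3) / total
        assert ge2 == pytest.approx(0.5, abs=0.02)
        assert ge3 == pytest.approx(0.25, abs=0.02)

    def test_degeneracy_matches_binomial_oracle(self):
        n = 100_000
        array = simulate_telomere_array(ModelParams(degeneracy=0.15), n, seed=7)
        n_other = array.unit_classes().count("other")
        # binomial oracle: Binomial(n, 0.15); allow 4 sigma
        sigma = (n * 0.15 * 0.85) ** 0.5
        assert abs(n_other - 0.15 * n) < 4 * sigma

    def test_allele_labels_conserved_without_degeneracy(self):
        array = simulate_telomere_array(
            ModelParams(p_x_wt=0.3, p_x_var=0.6, rho=0.4, degeneracy=0.0),
            20_000,
            seed=3,
        )
        n_var_label = array.alleles.count("var")
        n_var_unit = array.hexamers.count("TTAGGT")
        assert n_var_label == n_var_unit
        assert array.n_units == 20_000

    def test_run_length_law_chi_square(self):
        """Variant run lengths follow the geometric law with P(Add)."""
        p_x, rho = 0.4, 0.5
        params = ModelParams(p_x_wt=p_x, p_x_var=p_x, rho=rho, degeneracy=0.0)
        array = simulate_telomere_array(params, 100_000, seed=11)
        counts = RunLengthTable.from_unit_classes(array.unit_classes()).runs["var"]
        p_add = forward_p_add(p_x, rho)
        max_bin = 8  # pool the tail so every expected count is large
        total = sum(counts.values())
        observed = [counts.get(x, 0) for x in range(1, max_bin)]
        observed.append(total - sum(observed))
        expected = [
            total * p_add ** (x - 1) * (1 - p_add) for x in range(1, max_bin)
        ]
        expected.append(total - sum(expected))
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    @pytest.mark.parametrize(
        "kwargs", [{"p_x_wt": 1.2}, {"rho": -0.1}, {"degeneracy": 2.0}]
    )
    def test_invalid_probabilities_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_n_units_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_telomere_array(ModelParams(), 0, seed=1)

    def test_truth_sidecar_round_trips(self, tmp_path):
        array = simulate_telomere_array(ModelParams(), 50, seed=5)
        path = tmp_path / "truth.tsv"
        array.write_truth(path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "unit_index\thexamer\tallele"
        assert len(lines) == 51
        idx, hexamer, allele = lines[10].split("\t")
        assert (int(idx), hexamer, allele) == (9, array.hexamers[9], array.alleles[9])


class TestWgsReads:
    def test_error_free_reads_are_array_substrings(self):
        array = simulate_telomere_array(
            ModelParams(p_x_wt=0.5, p_x_var=0.5, degeneracy=0.1), 1000, seed=1
        )
        reads = simulate_wgs_reads(
            array,
            ReadSimParams(n_reads=200, error_rate_head=0.0, error_rate_tail=0.0, seed=2),
        )
        seq = array.sequence
        for read in reads:
            assert read.bases in seq or reverse_complement(read.bases) in seq

    def test_zero_reads_gives_empty_output(self):
        array = simulate_telomere_array(ModelParams(), 100, seed=1)
        assert simulate_wgs_reads(array, ReadSimParams(n_reads=0, seed=1)) == []

    def test_array_shorter_than_read_length_is_an_error(self):
        array = simulate_telomere_array(ModelParams(), 10, seed=1)  # 60 bases
        with pytest.raises(ValueError, match="read_length"):
            simulate_wgs_reads(array, ReadSimParams(read_length=150, n_reads=1))

    def test_mismatch_rates_match_configured_error_model(self):
        head, tail = 0.001, 0.02
        array = simulate_telomere_array(ModelParams(degeneracy=0.0), 5000, seed=6)
        params = ReadSimParams(
            n_reads=5000, error_rate_head=head, error_rate_tail=tail, seed=9
        )
        reads = simulate_wgs_reads(array, params)
        seq = array.sequence
        mism = {"head": 0, "tail": 0}
        trials = {"head": 0, "tail": 0}
        for read in reads:
            meta = dict(kv.split("=") for kv in read.read_id.split("|")[1:])
            start = int(meta["start"])
            src = seq[start : start + params.read_length]
            if meta["strand"] == "-":
                src = reverse_complement(src)
            for pos, (a, b) in enumerate(zip(read.bases, src)):
                region = "head" if pos < params.trim_point else "tail"
                trials[region] += 1
                mism[region] += a != b
        for region, rate in (("head", head), ("tail", tail)):
            observed = mism[region] / trials[region]
            sigma = (rate * (1 - rate) / trials[region]) ** 0.5
            assert abs(observed - rate) < 5 * sigma

    def test_quality_strings_encode_generating_rates(self):
        array = simulate_telomere_array(ModelParams(), 100, seed=1)
        params = ReadSimParams(
            n_reads=1, error_rate_head=0.001, error_rate_tail=0.02, seed=1
        )
        read = simulate_wgs_reads(array, params)[0]
        quals = list(read.qualities)
        assert all(q == 30 for q in quals[:60])  # -10*log10(0.001)
        assert all(q == 17 for q in quals[60:])  # -10*log10(0.02)

    def test_tail_rate_below_head_rate_rejected(self):
        with pytest.raises(ValueError, match="tail"):
            ReadSimParams(error_rate_head=0.01, error_rate_tail=0.001)

    def test_identical_seed_gives_byte_identical_fastq(self, tmp_path):
        array = simulate_telomere_array(ModelParams(), 2000, seed=4)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            reads = simulate_wgs_reads(array, ReadSimParams(n_reads=500, seed=77))
            path = tmp_path / name
            write_fastq(reads, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()


def single_permutation_params(perm, n_reads=50, seed=0, **kwargs):
    return TerminalSimParams(
        permutation_weights={perm: 1.0}, n_reads=n_reads, seed=seed, **kwargs
    )


class TestTerminalReads:
    def test_wild_type_register_structure(self):
        params = TerminalSimParams(
            permutation_weights={"GGTTAG": 1.0},
            tail_lengths={7: 1.0},
            n_reads=30,
            seed=1,
        )
        for read in simulate_terminal_reads(params):
            assert "GGGGGGG" + "CTAACC" in read.bases

    def test_variant_register_follows_g_run(self):
        params = TerminalSimParams(
            permutation_weights={"GGTTTA": 1.0},
            tail_lengths={8: 1.0},
            n_reads=30,
            seed=2,
        )
        for read in simulate_terminal_reads(params):
            idx = read.bases.index("G" * 8)
            assert read.bases[idx + 8 : idx + 14] == "TAAACC"

    def test_all_junk_passes_no_filter(self):
        reads = simulate_terminal_reads(
            TerminalSimParams(junk_fraction=1.0, n_reads=200, seed=3)
        )
        spec = spectrum(reads)
        assert spec.n_passing == 0
        assert sum(spec.rejections.values()) == 200

    def test_junk_rejection_reasons_match_construction(self):
        reads = simulate_terminal_reads(
            TerminalSimParams(junk_fraction=1.0, n_reads=300, seed=4)
        )
        from telovar import filter_terminal_read

        for read in reads:
            intended = read.read_id.split("reason=")[1]
            ok, reason = filter_terminal_read(read)
            assert not ok
            assert reason == intended

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TerminalSimParams(permutation_weights={"GGTTAG": 0.5})

    def test_unknown_permutation_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            TerminalSimParams(permutation_weights={"AAAAAA": 1.0})

    def test_default_weights_are_a_distribution(self):
        params = TerminalSimParams()
        assert sum(params.permutation_weights.values()) == pytest.approx(1.0)

    def test_terminal_reads_reproducible(self):
        a = simulate_terminal_reads(TerminalSimParams(n_reads=100, seed=5))
        b = simulate_terminal_reads(TerminalSimParams(n_reads=100, seed=5))
        assert [(r.read_id, r.bases) for r in a] == [(r.read_id, r.bases) for r in b]


def test_symmetric_model_gives_half_variant_fraction():
    """With p_x_wt == p_x_var and rho = 0.5 the variant unit fraction is 0.5."""
    params = ModelParams(p_x_wt=0.7, p_x_var=0.7, rho=0.5, degeneracy=0.0)
    counts = collections.Counter()
    for seed in range(5):
        array = simulate_telomere_array(params, 20_000, seed=seed)
        counts.update(array.alleles)
    total = counts["wt"] + counts["var"]
    assert counts["var"] / total == pytest.approx(0.5, abs=0.02)
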