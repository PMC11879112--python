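"""The simulator must produce reproducible amplicon read pairs whose truth
(end site, tail length) is exactly encoded in the sequences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotail._util import revcomp
from mitotail.simulate import (
    CAPTURE_ADAPTOR,
    GeneSpec,
    SimConfig,
    TailModel,
    build_amplicon,
    build_toy_reference,
    sample_transcript_truths,
    sequence_pair,
    simulate_library,
)


def _cfg(**kw):
    defaults = dict(
        n_pairs=10,
        end_usage={"canonical": 1.0, "alternate": 0.0, "other": 0.0},
        tail_model=TailModel("fixed", length=51),
        seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestToyReference:
    def test_deterministic_and_guarded(self):
        a = build_toy_reference(seed=1, length=2000, gene_specs=[GeneSpec("g", 1200)])
        b = build_toy_reference(seed=1, length=2000, gene_specs=[GeneSpec("g", 1200)])
        assert a.sequence == b.sequence
        assert len(a.sequence) == 2000
        assert a.genes[0].canonical_end == 1200
        # canonical terminal base is T (sense U) and the guarded window
        # upstream carries no A run of length >= 2
        assert a.sequence[1200] == "T"
        assert "AA" not in a.sequence[1196:1200]

    def test_minus_strand_guard(self):
        ref = build_toy_reference(seed=2, gene_specs=[GeneSpec("m", 700, strand="-")])
        assert ref.sequence[700] == "A"  # sense terminal base is T/U
        assert ref.genes[0].terminal_base == "T"

    def test_gene_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            build_toy_reference(seed=1, length=2000, gene_specs=[GeneSpec("g", 2500)])

    def test_overlapping_genes_named_in_error(self):
        with pytest.raises(ValueError, match="geneA.*geneB|geneB.*geneA"):
            build_toy_reference(
                seed=1,
                length=2000,
                gene_specs=[GeneSpec("geneA", 1200), GeneSpec("geneB", 1250)],
            )


class TestTruthSampling:
    def test_pure_canonical(self, plus_gene):
        truths = sample_transcript_truths(_cfg(n_pairs=100), plus_gene)
        assert len(truths) == 100
        assert all(end == plus_gene.canonical_end for end, _ in truths)

    def test_fixed_tail_length(self, plus_gene):
        truths = sample_transcript_truths(_cfg(n_pairs=50), plus_gene)
        assert all(tail == 51 for _, tail in truths)

    def test_pure_alternate_is_three_upstream(self, plus_gene):
        cfg = _cfg(end_usage={"canonical": 0.0, "alternate": 1.0, "other": 0.0})
        truths = sample_transcript_truths(cfg, plus_gene)
        assert all(end == plus_gene.canonical_end - 3 for end, _ in truths)

    def test_minus_strand_alternate_is_downstream_in_ref_coords(self, minus_gene):
        cfg = _cfg(end_usage={"canonical": 0.0, "alternate": 1.0, "other": 0.0})
        truths = sample_transcript_truths(cfg, minus_gene)
        assert all(end == minus_gene.canonical_end + 3 for end, _ in truths)

    def test_empirical_fraction_within_three_binomial_sd(self, plus_gene):
        p = 0.7
        n = 10_000
        cfg = _cfg(
            n_pairs=n,
            end_usage={"canonical": p, "alternate": 0.3, "other": 0.0},
            seed=17,
        )
        truths = sample_transcript_truths(cfg, plus_gene)
        frac = sum(end == plus_gene.canonical_end for end, _ in truths) / n
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(end_usage={"canonical": 0.6, "alternate": 0.3, "other": 0.0})


class TestTailModel:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_samples_are_nonnegative_ints_at_least_min(self, seed):
        rng = np.random.default_rng(seed)
        for model in (
            TailModel("fixed", length=25),
            TailModel("normal", mean=10, sd=15, min_length=3),
            TailModel("geometric", mean=20, min_length=5),
        ):
            draws = model.sample(rng, 200)
            assert draws.dtype.kind == "i"
            assert (draws >= model.min_length).all()

    def test_geometric_mean_close(self):
        rng = np.random.default_rng(0)
        model = TailModel("geometric", mean=30, min_length=5)
        assert abs(model.sample(rng, 50_000).mean() - 30) < 0.5


class TestAmplicon:
    def test_zero_tail_is_templated_plus_adaptor(self, toy_ref, plus_gene):
        cfg = _cfg()
        amp = build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end, 0, cfg)
        assert amp.endswith(CAPTURE_ADAPTOR)
        templated = amp[: -len(CAPTURE_ADAPTOR)]
        assert templated == toy_ref.sequence[
            plus_gene.canonical_end - cfg.gsp_distance + 1 : plus_gene.canonical_end + 1
        ]

    def test_exact_tail_insertion(self, toy_ref, plus_gene):
        amp = build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end, 3, _cfg())
        body = amp[: -len(CAPTURE_ADAPTOR)]
        assert body.endswith("AAA")
        assert not body[:-3].endswith("A")  # exactly three non-templated A's

    def test_canonical_templated_portion_ends_in_t(self, toy_ref, plus_gene):
        amp = build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end, 5, _cfg())
        templated = amp[: -len(CAPTURE_ADAPTOR) - 5]
        assert templated.endswith("T")

    def test_minus_strand_amplicon_is_sense(self, toy_ref, minus_gene):
        amp = build_amplicon(toy_ref, minus_gene, minus_gene.canonical_end, 4, _cfg())
        templated = amp[: -len(CAPTURE_ADAPTOR) - 4]
        assert templated.endswith("T")
        assert templated == revcomp(
            toy_ref.sequence[
                minus_gene.canonical_end : minus_gene.canonical_end + _cfg().gsp_distance
            ]
        )

    def test_end_upstream_of_primer_rejected(self, toy_ref, plus_gene):
        with pytest.raises(ValueError, match="primer"):
            build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end - 95, 3, _cfg())


class TestSequencing:
    def test_error_free_reads_are_template_prefixes(self, toy_ref, plus_gene):
        cfg = _cfg()
        amp = build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end, 51, cfg)
        pair = sequence_pair(amp, cfg)
        full = amp + cfg.sequencing_adapter
        assert pair.r1_seq == full[: cfg.read_length]
        assert pair.r2_seq == (revcomp(amp) + cfg.sequencing_adapter)[: cfg.read_length]

    def test_error_free_overlap_is_consistent(self, toy_ref, plus_gene):
        cfg = _cfg(read_length=120)
        amp = build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end, 10, cfg)
        assert len(amp) > cfg.read_length  # reads sample opposite amplicon ends
        pair = sequence_pair(amp, cfg)
        assert pair.r1_seq == amp[: cfg.read_length]
        assert revcomp(pair.r2_seq) == amp[-cfg.read_length :]
        # the region covered by both reads is identical base for base
        overlap = 2 * cfg.read_length - len(amp)
        assert overlap > 0
        assert pair.r1_seq[-overlap:] == revcomp(pair.r2_seq)[:overlap]

    def test_read_length_validation(self, toy_ref, plus_gene):
        cfg = _cfg(read_length=500)
        amp = build_amplicon(toy_ref, plus_gene, plus_gene.canonical_end, 5, cfg)
        with pytest.raises(ValueError, match="read_length"):
            sequence_pair(amp, cfg)


class TestLibrary:
    def test_truth_table_conservation(self, toy_ref):
        cfg = _cfg(n_pairs=37)
        pairs, truth = simulate_library(toy_ref, cfg)
        assert len(pairs) == len(truth) == cfg.n_pairs
        assert truth["read_id"].is_unique

    def test_rerun_is_byte_identical(self, toy_ref, tmp_path):
        from mitotail.io import write_fastq_pairs

        cfg = _cfg(n_pairs=20, substitution_error_rate=0.01)
        for tag in ("a", "b"):
            pairs, _ = simulate_library(toy_ref, cfg)
            write_fastq_pairs(pairs, tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()
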