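"""Generator invariants: determinism, bookkeeping identities, distributions."""

import math

import numpy as np
import pytest

from tailatlas.simulate import (
    CONDITIONS,
    EmitConfig,
    GeneConditionParams,
    MaturationModel,
    ReferenceConfig,
    SampleSpec,
    default_maturation_model,
    emit_reads,
    generate_reference,
    make_barcodes,
    sample_tail,
    simulate,
    write_dataset,
)


def test_reference_gene_counts_and_mt_placement():
    genome = generate_reference(ReferenceConfig(n_nuclear_genes=20, n_mt_genes=5), rng_seed=1)
    assert len(genome.genes) == 25
    assert len(genome.mt_genes) == 5
    assert all(genome.genes[g].contig == genome.mt_contig for g in genome.mt_genes)
    assert all(len(genome.genes[g].exons) == 1 for g in genome.mt_genes)
    assert any(len(genome.genes[g].exons) > 1 for g in genome.nuclear_genes)
    assert all(m.spliced_length >= 200 for m in genome.genes.values())


def test_reference_deterministic_and_byte_identical(tmp_path):
    cfg = ReferenceConfig(n_nuclear_genes=5, n_mt_genes=2)
    ds1 = simulate(seed=42, reference_config=cfg,
                   model_overrides={"base_abundance": 5.0, "mt_abundance": 3.0})
    ds2 = simulate(seed=42, reference_config=cfg,
                   model_overrides={"base_abundance": 5.0, "mt_abundance": 3.0})
    p1 = write_dataset(ds1, tmp_path / "a")
    p2 = write_dataset(ds2, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_zero_mt_genes_is_an_error():
    with pytest.raises(ValueError, match="mitochondrial"):
        generate_reference(ReferenceConfig(n_mt_genes=0), rng_seed=1)


def test_oversized_layout_raises_sizing_error():
    from tailatlas.simulate import SizingError

    cfg = ReferenceConfig(n_nuclear_genes=5000, max_contig_length=10_000)
    with pytest.raises(SizingError):
        generate_reference(cfg, rng_seed=1)


@pytest.fixture(scope="module")
def small_genome_module():
    return generate_reference(ReferenceConfig(n_nuclear_genes=4, n_mt_genes=1), rng_seed=2)


def _single_param_model(genome, **kwargs):
    defaults = dict(abundance=10.0, meanlog=math.log(80), sdlog=0.25)
    defaults.update(kwargs)
    p = GeneConditionParams(**defaults)
    return MaturationModel(params={g: {c: p for c in CONDITIONS} for g in genome.genes})


def test_fully_deadenylated_fraction_one_always_empty(small_genome_module, rng):
    model = _single_param_model(small_genome_module, frac_deadenylated=1.0)
    gene = small_genome_module.nuclear_genes[0]
    assert all(sample_tail(gene, "GV", model, rng) == "" for _ in range(200))


def test_zero_nonA_rates_give_all_A_tails(small_genome_module, rng):
    model = _single_param_model(small_genome_module)
    gene = small_genome_module.nuclear_genes[0]
    tails = [sample_tail(gene, "GV", model, rng) for _ in range(200)]
    assert all(set(t) == {"A"} for t in tails)


def test_tail_geometric_mean_recovers_lognormal_median(small_genome_module, rng):
    model = _single_param_model(small_genome_module, meanlog=math.log(80), sdlog=0.25)
    gene = small_genome_module.nuclear_genes[0]
    lengths = np.array([len(sample_tail(gene, "GV", model, rng)) for _ in range(10_000)])
    geo = math.exp(np.log(lengths[lengths > 0]).mean())
    assert abs(geo - 80) / 80 < 0.02


def test_nonA_insertions_preserve_drawn_length(small_genome_module, rng):
    model = _single_param_model(
        small_genome_module, p_nonA_5p=0.5, p_nonA_internal=0.5, p_nonA_3p=0.5
    )
    gene = small_genome_module.nuclear_genes[0]
    for _ in range(300):
        tail = sample_tail(gene, "GV", model, rng)
        assert set(tail) <= set("ACGT")
        # at 80 nt median, non-A stretches never dominate the tail
        assert tail.count("A") > 0


def test_mt_params_must_match_across_conditions(small_genome_module):
    model = default_maturation_model(small_genome_module)
    mt = small_genome_module.mt_genes[0]
    byc = model.params[mt]
    first = byc[CONDITIONS[0]]
    assert all(byc[c] == first for c in CONDITIONS)
    # and the validator enforces it
    broken = {g: dict(v) for g, v in model.params.items()}
    broken[mt] = dict(broken[mt])
    broken[mt]["GV"] = GeneConditionParams(99.0, math.log(45), 0.25)
    with pytest.raises(ValueError, match="identical parameters"):
        MaturationModel(params=broken).validate(small_genome_module)


def _emit(genome, model, seed, **overrides):
    samples = [
        SampleSpec("s1", "bc01", "in_vivo_MII"),
        SampleSpec("s2", "bc02", "in_vitro_MII"),
    ]
    barcodes = make_barcodes(2, rng_seed=99)
    cfg = EmitConfig(samples=samples, **overrides)
    return emit_reads(genome, model, dict(zip(["bc01", "bc02"], barcodes.values())), cfg, seed)


def test_exact_mode_unit_count_equals_configured_abundance(small_genome_module):
    model = _single_param_model(small_genome_module, abundance=7.0)
    ds = _emit(small_genome_module, model, seed=3)
    expected = 7 * len(small_genome_module.genes) * 2  # two samples
    assert len(ds.truth) == expected


def test_truth_tail_length_equals_sequence_length(small_genome_module):
    model = _single_param_model(
        small_genome_module, p_nonA_internal=0.3, frac_deadenylated=0.2
    )
    ds = _emit(small_genome_module, model, seed=4)
    assert (ds.truth.tail_length == ds.truth.tail_seq.fillna("").str.len()).all()


def test_concatenation_bookkeeping(small_genome_module):
    model = _single_param_model(small_genome_module, abundance=30.0)
    ds = _emit(small_genome_module, model, seed=5, p_concat=0.1)
    two_unit_reads = (ds.truth.groupby("read_id").size() == 2).sum()
    assert two_unit_reads == (ds.truth.unit_index == 1).sum()
    assert len(ds.reads) + two_unit_reads == len(ds.truth)


def test_orientation_fraction_within_binomial_bound(small_genome_module):
    model = _single_param_model(small_genome_module, abundance=100.0)
    ds = _emit(small_genome_module, model, seed=6, p_reverse=0.5)
    reads = ds.truth.drop_duplicates("read_id")
    n = len(reads)
    frac = reads.reverse_oriented.mean()
    assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / n)


def test_error_free_reads_end_tail_at_barcode(small_genome_module):
    model = _single_param_model(small_genome_module)
    ds = _emit(small_genome_module, model, seed=7, p_concat=0.0, p_reverse=0.0)
    bc = {s.barcode_id: ds.barcodes[s.barcode_id] for s in ds.config.samples}
    for read, (_, row) in zip(ds.reads[:50], ds.truth.iterrows()):
        body_tail_end = read.sequence.find(bc["bc01" if row["sample"] == "s1" else "bc02"])
        clean = read.sequence[len(ds.config.adapter5) : body_tail_end]
        assert clean.endswith(row.tail_seq)
        assert len(clean) == row.clean_length


def test_empty_barcode_set_rejected(small_genome_module):
    model = _single_param_model(small_genome_module)
    cfg = EmitConfig(samples=[SampleSpec("s1", "bc01", "GV")])
    with pytest.raises(ValueError, match="barcode"):
        emit_reads(small_genome_module, model, {}, cfg, rng_seed=1)
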