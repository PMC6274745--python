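import numpy as np
import pandas as pd
import pytest

from bovlnc import io as bio
from bovlnc.coding_potential import find_longest_orf
from bovlnc.models import ValidationError
from bovlnc.synthetic_data import (
    SimConfig,
    SizingError,
    _nb_draw,
    generate_annotation,
    generate_counts,
    generate_sequences,
)


class TestDeterminism:
    def test_annotation_bytes_identical(self, tmp_path, sim_config):
        paths = []
        for run in ("a", "b"):
            ref, asm, _ = generate_annotation(sim_config)
            p_ref, p_asm = tmp_path / f"ref_{run}.gtf", tmp_path / f"asm_{run}.gtf"
            bio.write_gtf(ref, p_ref)
            bio.write_gtf(asm, p_asm)
            paths.append((p_ref.read_bytes(), p_asm.read_bytes()))
        assert paths[0] == paths[1]

    def test_fasta_bytes_identical(self, tmp_path, sim_config, sim_data):
        truth = sim_data["truth"]
        for run in ("a", "b"):
            bio.write_fasta(generate_sequences(sim_config, truth), tmp_path / f"{run}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_counts_identical(self, sim_config, sim_data):
        cm2, design2 = generate_counts(sim_config, sim_data["truth"])
        assert cm2.counts.equals(sim_data["counts"].counts)
        assert design2.equals(sim_data["design"])

    def test_different_seeds_differ(self, sim_data):
        cfg2 = SimConfig(seed=12)
        _, _, truth2 = generate_annotation(cfg2)
        cm2, _ = generate_counts(cfg2, truth2)
        assert not cm2.counts.equals(sim_data["counts"].counts)


class TestTruthConsistency:
    def test_ids_unique_and_cross_referenced(self, sim_data):
        truth, assembled, reference = sim_data["truth"], sim_data["assembled"], sim_data["reference"]
        assert truth.features.index.is_unique
        assert truth.genes.index.is_unique
        assert truth.transcripts.index.is_unique
        # every assembled transcript has a truth row and vice versa
        assert set(truth.features.index) == set(assembled.transcripts)
        # every sequence id resolves to an annotation transcript
        all_tx = set(assembled.transcripts) | set(reference.transcripts)
        assert set(truth.transcripts.index) <= all_tx

    def test_sequence_lengths_match_annotation(self, sim_data):
        seqs, truth = sim_data["seqs"], sim_data["truth"]
        for tid, row in truth.transcripts.iterrows():
            assert len(seqs[tid]) == row["length"]

    def test_every_class_planted_at_least_five_times(self, sim_data):
        lnc = sim_data["truth"].features.query("feature_type == 'lncrna_candidate'")
        assert (lnc["positional_class"].value_counts() >= 5).all()
        codes = sim_data["truth"].features["expected_code"].value_counts()
        for code in "=cjioux":
            assert codes.get(code, 0) >= 4, code

    def test_short_decoys_planted(self, sim_data):
        short = sim_data["truth"].features.query("feature_type == 'short_decoy'")
        assert len(short) >= 3
        assert (short["length"] < 200).all()

    def test_intergenic_only_mix_keeps_all_lncrnas_far_from_genes(self):
        from bovlnc.positional import PositionalClass

        mix = {c: 0.0 for c in PositionalClass}
        mix[PositionalClass.INTERGENIC_GT1KB] = 1.0
        cfg = SimConfig(seed=5, n_lncrna=60, class_mix=mix, planted_cis=[], planted_lfc=[])
        ref, asm, truth = generate_annotation(cfg)
        coding = ref.subset_biotypes(["protein_coding"])
        for fid, row in truth.features.iterrows():
            if row["feature_type"] != "lncrna_candidate":
                continue
            lnc = asm.transcripts[fid]
            gaps = [
                max(lnc.start - ge, gs - lnc.end, 0)
                for g in coding.genes()
                for c, gs, ge in [coding.gene_span(g)]
                if c == lnc.chrom
            ]
            assert min(gaps) > 1000


class TestSequences:
    def test_coding_orf_covers_half_of_transcript(self, sim_data):
        truth, seqs = sim_data["truth"], sim_data["seqs"]
        coding_ids = truth.transcripts.query("coding_label == 'coding'").index
        for tid in list(coding_ids)[:40]:
            _, _, ln = find_longest_orf(seqs[tid])
            assert ln >= 0.5 * len(seqs[tid])

    def test_noncoding_hexamer_mean_below_coding(self, sim_data):
        from bovlnc.coding_potential import build_hexamer_tables, hexamer_score

        truth, seqs = sim_data["truth"], sim_data["seqs"]
        tx = truth.transcripts
        coding = [seqs[i] for i in tx.query("coding_label == 'coding'").index[:60]]
        noncoding = [seqs[i] for i in tx.query("coding_label == 'noncoding'").index[:60]]
        ct, nt = build_hexamer_tables(coding, noncoding)
        mean_c = np.mean([hexamer_score(s, ct, nt) for s in coding])
        mean_n = np.mean([hexamer_score(s, ct, nt) for s in noncoding])
        assert mean_n < mean_c


class TestCounts:
    def test_nb_moments_match_parameterization(self):
        """Realized mean/variance over many draws match mu and
        mu + mu^2 * dispersion within 5%."""
        rng = np.random.default_rng(42)
        mu, disp = 150.0, 0.05
        draws = _nb_draw(rng, np.full(20_000, mu), disp)
        assert np.mean(draws) == pytest.approx(mu, rel=0.05)
        assert np.var(draws) == pytest.approx(mu + mu**2 * disp, rel=0.05)

    def test_dimensions_and_design(self, sim_data):
        cm, design = sim_data["counts"], sim_data["design"]
        assert cm.counts.shape[1] == 36
        assert design.groupby(["treatment", "day"]).size().eq(6).all()
        assert design.index.is_unique

    def test_nonpositive_dispersion_rejected(self, sim_data):
        cfg = SimConfig(seed=1, nb_dispersion=0.0)
        with pytest.raises(ValidationError):
            generate_counts(cfg, sim_data["truth"])

    def test_planted_lfc_realized_in_group_means(self, sim_data):
        """Planted log2FCs shift the normalized group means by roughly the
        planted amount."""
        truth = sim_data["truth"]
        cm, design = sim_data["counts"], sim_data["design"]
        for _, row in truth.planted_lfc.iterrows():
            fid = row["feature_id"]
            libs_a = design.index[(design["treatment"] == row["treatment"]) & (design["day"] == row["dayA"])]
            libs_b = design.index[(design["treatment"] == row["treatment"]) & (design["day"] == row["dayB"])]
            est = np.log2(cm.counts.loc[fid, libs_b].mean() + 0.5) - np.log2(
                cm.counts.loc[fid, libs_a].mean() + 0.5
            )
            assert est == pytest.approx(row["log2fc"], abs=0.6)

    def test_realized_cis_correlation_near_target_on_average(self):
        """Mean realized r of planted pairs over several seeds is within
        +-0.05 of the 0.9 target at n=18."""
        from bovlnc.cis_target import pearson_with_p
        from bovlnc.expression import size_factors

        rs = []
        for seed in range(8):
            cfg = SimConfig(seed=100 + seed)
            _, _, truth = generate_annotation(cfg)
            cm, design = generate_counts(cfg, truth)
            sf = size_factors(cm)
            expr = np.log2(cm.counts / sf + 1.0)
            libs = design.index[design["treatment"] == "LSO"]
            for _, row in truth.planted_cis.iterrows():
                if row["target_r"] >= 0.9:
                    r, _ = pearson_with_p(
                        expr.loc[row["lncrna_id"], libs], expr.loc[row["gene_id"], libs]
                    )
                    rs.append(r)
        assert np.mean(rs) == pytest.approx(0.9, abs=0.05)


class TestErrors:
    def test_sizing_error_names_the_feature(self):
        cfg = SimConfig(seed=1, chrom_length=20_000, n_chromosomes=1)
        with pytest.raises(SizingError, match="chr1"):
            generate_annotation(cfg)

    def test_bad_class_mix_rejected(self):
        from bovlnc.positional import PositionalClass

        mix = {c: 0.5 for c in PositionalClass}
        with pytest.raises(ValidationError, match="sum"):
            SimConfig(seed=1, class_mix=mix).validate()

    def test_cis_pair_gene_mismatch_rejected(self):
        cfg = SimConfig(seed=1, planted_cis=[("LNC0001", "NOPE", 0.9)])
        with pytest.raises(ValidationError, match="unknown feature"):
            generate_annotation(cfg)
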