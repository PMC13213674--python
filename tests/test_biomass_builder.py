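"""Biomass construction: monomer fractions, mass closure, maintenance terms."""

import numpy as np
import pytest

from hydrogem import synthetic_data
from hydrogem.biomass_builder import (
    AMINO_ACIDS,
    DEFAULT_MW_TABLE,
    DNTPS,
    NTPS,
    BiomassEquation,
    MacroComposition,
    MaintenanceParams,
    MonomerProfile,
    build_biomass,
    monomer_fractions_from_cds,
    normalize_biomass,
)

UNIFORM_MONOMERS = MonomerProfile(
    amino_acid_fractions={a: 1 / 20 for a in AMINO_ACIDS},
    dntp_fractions={d: 0.25 for d in DNTPS},
    ntp_fractions={n: 0.25 for n in NTPS},
)


def write_fasta(path, records):
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in records))
    return path


class TestMonomerFractionsFromCds:
    def test_symmetric_cds_gives_uniform_dna(self, tmp_path):
        fasta = write_fasta(tmp_path / "a.fa", [("cds1", "ATGC")])
        fractions = monomer_fractions_from_cds(fasta, "dna")
        assert fractions == pytest.approx(
            {"datp": 0.25, "dctp": 0.25, "dgtp": 0.25, "dttp": 0.25}
        )

    def test_double_strand_symmetry(self, tmp_path):
        fasta = write_fasta(tmp_path / "a.fa", [("cds1", "AAAA")])
        fractions = monomer_fractions_from_cds(fasta, "dna")
        assert fractions["datp"] == pytest.approx(0.5)
        assert fractions["dttp"] == pytest.approx(0.5)
        assert fractions["dgtp"] == 0.0 and fractions["dctp"] == 0.0

    def test_rna_fractions_match_hand_count(self, tmp_path):
        # coding strands pooled: A 6, C 4, G 4, T 4 over three CDS records
        fasta = write_fasta(
            tmp_path / "three.fa",
            [("c1", "ATGACC"), ("c2", "TTAGGA"), ("c3", "ACTCGA")],
        )
        fractions = monomer_fractions_from_cds(fasta, "rna")
        total = 18
        assert fractions["atp"] == pytest.approx(6 / total)
        assert fractions["ctp"] == pytest.approx(4 / total)
        assert fractions["gtp"] == pytest.approx(4 / total)
        assert fractions["utp"] == pytest.approx(4 / total)

    def test_n_bases_skipped(self, tmp_path):
        fasta = write_fasta(tmp_path / "n.fa", [("c", "ANNA")])
        fractions = monomer_fractions_from_cds(fasta, "rna")
        assert fractions["atp"] == pytest.approx(1.0)

    def test_empty_fasta_is_input_error(self, tmp_path):
        fasta = tmp_path / "empty.fa"
        fasta.write_text("")
        with pytest.raises(ValueError, match="empty"):
            monomer_fractions_from_cds(fasta, "dna")

    def test_non_nucleotide_is_parse_error(self, tmp_path):
        fasta = write_fasta(tmp_path / "bad.fa", [("c", "ATXG")])
        with pytest.raises(ValueError, match="non-nucleotide"):
            monomer_fractions_from_cds(fasta, "dna")


class TestBuildBiomass:
    def test_pure_glycogen_closed_form(self):
        """Single-component closed form: S = 1000 / residue mass."""
        macro = MacroComposition(protein=0, dna=0, rna=0, glycogen=1.0,
                                 lipid=0, cell_wall=0, lps=0, ions=0,
                                 soluble_pool=0)
        equation, _ = build_biomass(macro, UNIFORM_MONOMERS)
        residue = DEFAULT_MW_TABLE["glucosyl"] - DEFAULT_MW_TABLE["h2o"]
        assert equation.precursors["glucosyl"] == pytest.approx(
            1000.0 / residue, rel=1e-9
        )
        assert equation.precursors["glucosyl"] == pytest.approx(6.168, abs=2e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_mass_closure_for_random_compositions(self, seed):
        macro, monomer = synthetic_data.synth_composition(seed)
        equation, _ = build_biomass(macro, monomer)
        assert equation.net_mass(DEFAULT_MW_TABLE) == pytest.approx(1.0, abs=1e-6)

    def test_maintenance_defaults_in_built_reactions(self):
        macro, monomer = synthetic_data.synth_composition(5)
        equation, (biomass, atpm) = build_biomass(macro, monomer)
        atp = next(m for m in biomass.metabolites if m.id == "atp_c")
        gam_in_reaction = -biomass.metabolites[atp] - equation.precursors.get(
            "atp", 0.0
        )
        assert gam_in_reaction == pytest.approx(26.48, abs=1e-9)
        assert equation.maintenance.gam == 26.48
        assert atpm.id == "ATPM"
        assert atpm.lower_bound == pytest.approx(0.81)

    def test_monomer_scale_invariance(self):
        """Doubling every mole fraction leaves the coefficients unchanged:
        S_i depends on x_i only through x_i / sum_k x_k * M_residue,k."""
        _, monomer = synthetic_data.synth_composition(2)
        from hydrogem.biomass_builder import _polymer_coefficients

        ones, rel1 = _polymer_coefficients(
            0.5, monomer.amino_acid_fractions, DEFAULT_MW_TABLE, "h2o"
        )
        twos, rel2 = _polymer_coefficients(
            0.5,
            {k: 2 * v for k, v in monomer.amino_acid_fractions.items()},
            DEFAULT_MW_TABLE,
            "h2o",
        )
        for key in ones:
            assert twos[key] == pytest.approx(ones[key], rel=1e-12)
        assert rel2 == pytest.approx(rel1, rel=1e-12)

    def test_gam_terms_are_additive(self):
        macro, monomer = synthetic_data.synth_composition(3)
        eq_small, _ = build_biomass(
            macro, monomer, maintenance=MaintenanceParams(gam=1e-9, ngam=0.81)
        )
        eq_default, _ = build_biomass(macro, monomer)
        for key, value in eq_default.precursors.items():
            assert eq_small.precursors[key] == pytest.approx(value, rel=1e-9)

    def test_missing_mw_names_the_monomer(self):
        macro, monomer = synthetic_data.synth_composition(4)
        table = dict(DEFAULT_MW_TABLE)
        del table["glucosyl"]
        with pytest.raises(KeyError, match="glucosyl"):
            build_biomass(macro, monomer, mw_table=table)

    def test_invalid_composition_sum_rejected(self):
        bad = MacroComposition(protein=0.2, dna=0.01, rna=0.05, glycogen=0.02,
                               lipid=0.05, cell_wall=0.05, lps=0.01,
                               ions=0.005, soluble_pool=0.005)
        with pytest.raises(ValueError, match="outside"):
            bad.validate()


class TestNormalizeBiomass:
    def test_scaling_identity(self):
        """An equation carrying 2 g net mass has every coefficient halved."""
        glc_mw = DEFAULT_MW_TABLE["glucosyl"]
        eq = BiomassEquation(
            precursors={"glucosyl": 2000.0 / glc_mw}, byproducts={}
        )
        assert eq.net_mass(DEFAULT_MW_TABLE) == pytest.approx(2.0)
        normalized = normalize_biomass(eq, DEFAULT_MW_TABLE)
        assert normalized.precursors["glucosyl"] == pytest.approx(
            0.5 * eq.precursors["glucosyl"], rel=1e-12
        )

    def test_idempotent(self):
        macro, monomer = synthetic_data.synth_composition(6)
        eq, _ = build_biomass(macro, monomer)
        again = normalize_biomass(eq, DEFAULT_MW_TABLE)
        for key, value in eq.precursors.items():
            assert again.precursors[key] == pytest.approx(value, abs=1e-12)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_random_equation_recomputed_mass_is_one(self, seed):
        rng = np.random.default_rng(seed)
        monomers = ["glucosyl", "ala__L", "atp", "datp", "lipid"]
        eq = BiomassEquation(
            precursors={m: float(rng.uniform(0.1, 20)) for m in monomers},
            byproducts={"h2o": float(rng.uniform(0.1, 5)),
                        "ppi": float(rng.uniform(0.1, 2))},
        )
        normalized = normalize_biomass(eq, DEFAULT_MW_TABLE)
        # independent oracle: direct summation
        direct = (
            sum(s * DEFAULT_MW_TABLE[m] for m, s in normalized.precursors.items())
            - sum(s * DEFAULT_MW_TABLE[m] for m, s in normalized.byproducts.items())
        ) / 1000.0
        assert direct == pytest.approx(1.0, abs=1e-9)

    def test_non_positive_mass_rejected(self):
        eq = BiomassEquation(precursors={"h2o": 1.0},
                             byproducts={"glucosyl": 10.0})
        with pytest.raises(ValueError, match="net"):
            normalize_biomass(eq, DEFAULT_MW_TABLE)
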