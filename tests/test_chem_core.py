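"""Exact-mass arithmetic, formula enumeration and van Krevelen classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brewomics import chem_core
from brewomics.chem_core import (
    ANNOTATION_BOUNDS,
    DEFAULT_REGIONS,
    DEPROTONATION_MASS,
    MONOISOTOPIC_MASS,
    Constraints,
    FormulaError,
    MolecularFormula,
    classify_compound_class,
    dbe,
    deglycosylate,
    enumerate_formulas,
    ion_mz,
    load_library,
    load_regions,
    match_library,
    monoisotopic_mass,
    ppm_error,
    van_krevelen,
)

formulas = st.builds(
    MolecularFormula,
    C=st.integers(1, 40),
    H=st.integers(1, 80),
    N=st.integers(0, 4),
    O=st.integers(0, 20),
    S=st.integers(0, 2),
    P=st.integers(0, 1),
    Cl=st.integers(0, 1),
)


class TestMass:
    def test_carbon12_definition(self):
        assert monoisotopic_mass(MolecularFormula(C=1)) == 12.0

    def test_bisulfate_anion_reproduces_printed_value(self):
        # HSO4- as radical anion mass: neutral HSO4 plus one electron
        anion = monoisotopic_mass(MolecularFormula.parse("HSO4")) + chem_core.ELECTRON_MASS
        assert round(anion, 4) == 96.9601

    def test_sulfonolipid_neutral_mass(self):
        assert monoisotopic_mass(MolecularFormula.parse("C18H32SO6")) == pytest.approx(
            376.1920, abs=1e-4
        )

    def test_empty_formula_rejected(self):
        with pytest.raises(FormulaError):
            MolecularFormula()

    @settings(max_examples=50, derandomize=True)
    @given(formulas, formulas)
    def test_mass_additivity(self, a, b):
        assert monoisotopic_mass(a) + monoisotopic_mass(b) == pytest.approx(
            monoisotopic_mass(a.combine(b)), abs=1e-9
        )


class TestIonMz:
    def test_sulfuric_acid_deprotonated_is_bisulfate(self):
        assert round(ion_mz(MolecularFormula.parse("H2SO4")), 4) == 96.9601

    def test_printed_hede_sulfonate_mass_within_2ppm(self):
        theo = ion_mz(MolecularFormula.parse("C20H36SO6"))
        assert theo == pytest.approx(403.2160, abs=1e-4)
        assert abs(ppm_error(403.2152, theo)) <= 2.0

    @settings(max_examples=50, derandomize=True)
    @given(formulas)
    def test_deprotonation_offset_is_constant(self, f):
        assert ion_mz(f) - monoisotopic_mass(f) == pytest.approx(
            -DEPROTONATION_MASS, abs=1e-12
        )

    def test_hydrogen_free_formula_cannot_deprotonate(self):
        with pytest.raises(FormulaError):
            ion_mz(MolecularFormula(C=6))


class TestPpmError:
    @pytest.mark.parametrize(
        "obs,theo,expected", [(400.0, 400.0, 0.0), (400.0004, 400.0, 1.0)]
    )
    def test_definition(self, obs, theo, expected):
        assert ppm_error(obs, theo) == pytest.approx(expected, abs=1e-9)

    def test_printed_hode_sulfonate_within_5ppm(self):
        theo = ion_mz(MolecularFormula.parse("C18H32SO6"))
        assert abs(ppm_error(375.1832, theo)) <= 5.0

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestDbe:
    @pytest.mark.parametrize(
        "formula,expected",
        [("C6H6", 4.0), ("C18H32SO6", 3.0), ("CH4", 0.0)],
    )
    def test_examples(self, formula, expected):
        assert dbe(MolecularFormula.parse(formula)) == expected


class TestFormulaStrings:
    @settings(max_examples=100, derandomize=True)
    @given(formulas)
    def test_hill_round_trip(self, f):
        assert MolecularFormula.parse(f.hill()) == f

    def test_non_hill_order_accepted(self):
        assert MolecularFormula.parse("C18H32SO6") == MolecularFormula.parse("C18H32O6S")

    @pytest.mark.parametrize("bad", ["", "X4", "C-3H", "12C"])
    def test_unparseable_rejected(self, bad):
        with pytest.raises(FormulaError):
            MolecularFormula.parse(bad)


SMALL_BOUNDS = {
    "C": (1, 15), "H": (0, 30), "N": (0, 2), "O": (0, 8),
    "S": (0, 1), "P": (0, 0), "Cl": (0, 0),
}


def brute_force_formulas(mz, tol_ppm, bounds, constraints=Constraints()):
    """Independent nested-loop oracle for enumerate_formulas."""
    out = []
    (cl, ch), (hl, hh) = bounds["C"], bounds["H"]
    ranges = [range(bounds[e][0], bounds[e][1] + 1) for e in ("N", "O", "S", "P", "Cl")]
    for c in range(cl, ch + 1):
        for h in range(max(hl, 1), hh + 1):
            for n, o, s, p, clc in itertools.product(*ranges):
                m = (c * 12.0 + h * MONOISOTOPIC_MASS["H"] + n * MONOISOTOPIC_MASS["N"]
                     + o * MONOISOTOPIC_MASS["O"] + s * MONOISOTOPIC_MASS["S"]
                     + p * MONOISOTOPIC_MASS["P"] + clc * MONOISOTOPIC_MASS["Cl"])
                theo = m - DEPROTONATION_MASS
                if abs(mz - theo) > tol_ppm * 1e-6 * mz:
                    continue
                d = c + 1 + (n + p) / 2 - (h + clc) / 2
                if d < constraints.dbe_min or d > constraints.dbe_max or d != int(d):
                    continue
                if not constraints.hc_min <= h / c <= constraints.hc_max:
                    continue
                if o / c > constraints.oc_max:
                    continue
                out.append((c, h, n, o, s, p, clc))
    return sorted(out)


class TestEnumeration:
    def test_tight_tolerance_recovers_unique_formula(self):
        f = MolecularFormula.parse("C8H16O3S")
        cands = enumerate_formulas(ion_mz(f), 0.1, SMALL_BOUNDS)
        assert [c.formula for c in cands] == [f]

    def test_printed_sulfonate_contained_at_5ppm(self):
        bounds = {"C": (1, 30), "H": (0, 60), "N": (0, 2), "O": (0, 12),
                  "S": (0, 2), "P": (0, 0), "Cl": (0, 0)}
        cands = enumerate_formulas(403.2152, 5.0, bounds)
        assert MolecularFormula.parse("C20H36SO6") in [c.formula for c in cands]
        cands = enumerate_formulas(191.0742, 3.0, bounds)
        assert MolecularFormula.parse("C8H16SO3") in [c.formula for c in cands]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for mz in rng.uniform(120, 350, 100):
            got = sorted(
                (c.formula.C, c.formula.H, c.formula.N, c.formula.O,
                 c.formula.S, c.formula.P, c.formula.Cl)
                for c in enumerate_formulas(float(mz), 20.0, SMALL_BOUNDS)
            )
            assert got == brute_force_formulas(float(mz), 20.0, SMALL_BOUNDS), mz

    def test_candidates_sorted_by_abs_ppm(self):
        cands = enumerate_formulas(403.2152, 20.0, SMALL_BOUNDS | {"C": (1, 30), "H": (0, 60)})
        errs = [abs(c.ppm) for c in cands]
        assert errs == sorted(errs)

    def test_empty_result_is_not_an_error(self):
        assert enumerate_formulas(120.00001, 0.001, SMALL_BOUNDS) == []

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            enumerate_formulas(-1.0, 1.0)
        with pytest.raises(ValueError):
            enumerate_formulas(400.0, 0.0)

    @settings(max_examples=30, derandomize=True)
    @given(st.builds(MolecularFormula, C=st.integers(4, 30),
                     H=st.integers(6, 50), O=st.integers(0, 10),
                     N=st.integers(0, 3), S=st.integers(0, 1)))
    def test_round_trip_contains_query_formula(self, f):
        if f.dbe < 0 or f.dbe != int(f.dbe) or not 0.2 <= f.hc <= 3.1 or f.oc > 1.5:
            return
        cands = enumerate_formulas(ion_mz(f), 0.5, ANNOTATION_BOUNDS)
        assert f in [c.formula for c in cands]


class TestVanKrevelen:
    def test_glucose(self):
        assert van_krevelen(MolecularFormula.parse("C6H12O6")) == (1.0, 2.0)

    def test_sulfonolipid_ratios(self):
        oc, hc = van_krevelen(MolecularFormula.parse("C18H32SO6"))
        assert oc == pytest.approx(1 / 3) and hc == pytest.approx(16 / 9)

    @pytest.mark.parametrize("n", [3, 6, 9, 12])
    def test_cnh2non_family_invariance(self, n):
        assert van_krevelen(MolecularFormula(C=n, H=2 * n, O=n)) == (1.0, 2.0)

    def test_carbon_free_rejected(self):
        with pytest.raises(FormulaError):
            van_krevelen(MolecularFormula.parse("H2SO4"))


class TestCompoundClasses:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C20H38O3", "lipid-like"),                       # H/C 1.9, O/C 0.15
            ("C20H38SO3", "sulfonolipid-like"),
            ("C10H12NO6", "amino-sugar/Maillard-conjugate-like"),  # H/C 1.2, O/C 0.6
            ("C6H12O6", "carbohydrate-like"),
            ("C21H20O11", "polyphenol/glycoside-like"),
            ("C2H2", "unclassified"),
        ],
    )
    def test_region_table(self, formula, expected):
        assert classify_compound_class(MolecularFormula.parse(formula)) == expected

    @settings(max_examples=100, derandomize=True)
    @given(formulas)
    def test_total_and_deterministic(self, f):
        first = classify_compound_class(f)
        assert isinstance(first, str)
        assert classify_compound_class(f) == first

    def test_region_table_io(self, tmp_path):
        path = tmp_path / "regions.json"
        path.write_text(
            '[{"label": "lipid-like", "hc_min": 1.5, "hc_max": 2.3,'
            ' "oc_min": 0, "oc_max": 0.35, "predicate": "cho_only"}]'
        )
        regions = load_regions(path)
        assert classify_compound_class(MolecularFormula.parse("C20H38O3"), regions) == "lipid-like"


class TestDeglycosylation:
    def test_single_hexose_loss(self):
        out = deglycosylate(500.0, {"hexose": 162.0528})
        assert out[0].aglycone_mz == pytest.approx(337.9472, abs=1e-6)

    def test_hexose_residue_equals_anhydroglucose_mass(self):
        assert chem_core.DEFAULT_RESIDUES["hexose"] == pytest.approx(
            monoisotopic_mass(MolecularFormula.parse("C6H10O5")), abs=1e-4
        )

    def test_additivity_identity(self):
        aglycone = MolecularFormula.parse("C15H10O6")
        glycoside = aglycone.combine(MolecularFormula.parse("C6H10O5"))
        outs = deglycosylate(ion_mz(glycoside))
        hits = [o for o in outs if o.residue == "hexose" and o.multiplicity == 1]
        assert hits[0].aglycone_mz == pytest.approx(ion_mz(aglycone), abs=1e-9)

    def test_floor_and_multiplicity_cap(self):
        out = deglycosylate(500.0, {"hexose": 162.0528}, max_multiplicity=3, floor_mz=100.0)
        assert [o.multiplicity for o in out] == [1, 2]  # 3rd would fall below 100

    def test_empty_residue_set_rejected(self):
        with pytest.raises(ValueError):
            deglycosylate(500.0, {})


class TestLibraryMatching:
    LIB = [("quercetin", MolecularFormula.parse("C15H10O7")),
           ("rutin", MolecularFormula.parse("C27H30O16"))]

    def test_exact_query_matches_entry(self):
        hits = match_library([ion_mz(self.LIB[0][1])], self.LIB, tol_ppm=1.0)
        assert [h.name for h in hits] == ["quercetin"]

    def test_empty_query(self):
        assert match_library([], self.LIB, tol_ppm=1.0) == []

    def test_offset_beyond_tolerance(self):
        q = ion_mz(self.LIB[0][1]) * (1 + 10e-6)
        assert match_library([q], self.LIB, tol_ppm=5.0) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            match_library([300.0], [], tol_ppm=1.0)

    def test_library_file_io(self, tmp_path):
        p = tmp_path / "lib.tsv"
        p.write_text("# name\tformula\nquercetin\tC15H10O7\n")
        lib = load_library(p)
        assert lib == [("quercetin", MolecularFormula.parse("C15H10O7"))]
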