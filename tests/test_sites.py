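"""Fragment arithmetic, modification localization, protein mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chapmod.masses import PROTON, get_modification, peptide_monoisotopic_mass
from chapmod.records import SpectrumRecord
from chapmod.simulate import spike_modified_peptides
from chapmod.sites import (
    LocalizationError,
    MappingError,
    localize_site,
    map_to_protein,
    theoretical_fragments,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
TRI = get_modification("trimethyl")


class TestTheoreticalFragments:
    def test_ion_counts(self):
        b, y = theoretical_fragments("PEPTIDEK")
        assert len(b) == len(y) == 7

    @pytest.mark.parametrize("peptide", ["AK", "PEPTIDEK", "MKTAYIAKQRPK",
                                         "ACDEFGHIKLMNPQR"])
    def test_b_y_complementarity_closed_form(self, peptide):
        """b_i + y_(n-i) equals the singly-protonated precursor plus a proton."""
        b, y = theoretical_fragments(peptide)
        n = len(peptide)
        mh = peptide_monoisotopic_mass(peptide) + PROTON
        for i in range(1, n):
            assert b[i - 1] + y[n - i - 1] == pytest.approx(mh + PROTON, abs=1e-8)

    @given(st.text(alphabet=AA, min_size=2, max_size=15))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_b_y_complementarity_holds_for_random_short_peptides(self, peptide):
        b, y = theoretical_fragments(peptide)
        n = len(peptide)
        target = peptide_monoisotopic_mass(peptide) + 2 * PROTON
        assert all(
            abs(b[i - 1] + y[n - i - 1] - target) < 1e-8 for i in range(1, n)
        )

    def test_nterminal_modification_shifts_all_b_and_no_y(self):
        """A mod on residue 1 sits in every b ion and in no y_1..y_(n-1)."""
        pep = "KAAAR"
        b0, y0 = theoretical_fragments(pep)
        b1, y1 = theoretical_fragments(pep, [(1, TRI)])
        assert all(m1 == pytest.approx(m0 + TRI.delta_da) for m0, m1 in zip(b0, b1))
        assert y1 == pytest.approx(y0)

    def test_cterminal_modification_shifts_all_y_and_no_b(self):
        pep = "AAARK"
        b0, y0 = theoretical_fragments(pep)
        b1, y1 = theoretical_fragments(pep, [(5, TRI)])
        assert all(m1 == pytest.approx(m0 + TRI.delta_da) for m0, m1 in zip(y0, y1))
        assert b1 == pytest.approx(b0)

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            theoretical_fragments("AB1")


def _spectrum_for(peptide, site, mod=TRI, keep=1.0, rng=None, charge=2):
    b, y = theoretical_fragments(peptide, [(site, mod)])
    frags = [(mz, 100.0) for mz in b + y]
    if keep < 1.0:
        n_keep = max(1, int(round(keep * len(frags))))
        idx = rng.choice(len(frags), size=n_keep, replace=False)
        frags = [frags[i] for i in sorted(idx)]
    return SpectrumRecord(
        precursor_neutral_mass=peptide_monoisotopic_mass(peptide) + mod.delta_da,
        charge=charge,
        fragments=frags,
    )


class TestLocalize:
    def test_full_coverage_recovers_the_planted_site(self):
        pep = "AGKLSAKDEWR"  # K at 3 and 7; plant at 7
        assign = localize_site(_spectrum_for(pep, 7), pep, TRI)
        assert assign.peptide_site_index == 7
        assert assign.delta_score > 0
        assert not assign.ambiguous

    def test_single_lysine_chosen_regardless_of_fragments(self):
        pep = "AGKLSADEWR"
        spec = SpectrumRecord(
            precursor_neutral_mass=peptide_monoisotopic_mass(pep) + TRI.delta_da,
            charge=2, fragments=[(50.0, 1.0)],
        )
        assign = localize_site(spec, pep, TRI)
        assert assign.peptide_site_index == 3
        assert not assign.ambiguous

    def test_nondiscriminating_fragments_are_ambiguous(self):
        """Fragments common to both candidate ion series cannot pick a site."""
        pep = "AGKLSAKDEWR"
        b7, y7 = theoretical_fragments(pep, [(7, TRI)])
        b3, y3 = theoretical_fragments(pep, [(3, TRI)])
        common = sorted(set(round(m, 4) for m in b7 + y7)
                        & set(round(m, 4) for m in b3 + y3))
        spec = SpectrumRecord(
            precursor_neutral_mass=peptide_monoisotopic_mass(pep) + TRI.delta_da,
            charge=2, fragments=[(m, 1.0) for m in common],
        )
        assign = localize_site(spec, pep, TRI)
        assert assign.ambiguous
        assert assign.delta_score == 0.0

    def test_no_candidate_residue_errors(self):
        pep = "AGLSADEWR"
        spec = SpectrumRecord(
            precursor_neutral_mass=peptide_monoisotopic_mass(pep) + TRI.delta_da,
            charge=2, fragments=[(100.0, 1.0)],
        )
        with pytest.raises(LocalizationError, match="no residue"):
            localize_site(spec, pep, TRI)

    def test_precursor_mismatch_errors(self):
        pep = "AGKLSADEWR"
        spec = SpectrumRecord(
            precursor_neutral_mass=peptide_monoisotopic_mass(pep) + 1.0,
            charge=2, fragments=[(100.0, 1.0)],
        )
        with pytest.raises(LocalizationError, match="ppm"):
            localize_site(spec, pep, TRI)

    def test_localization_degrades_monotonically_with_fragment_coverage(self, rng):
        """Recovery at 100% >= 75% >= 50% fragment coverage."""
        pep = "AAKGLDSAKWTER"  # K3 vs K9
        rates = []
        for keep in (1.0, 0.75, 0.5):
            hits = 0
            trials = 120
            for _ in range(trials):
                spec = _spectrum_for(pep, 9, keep=keep, rng=rng)
                a = localize_site(spec, pep, TRI)
                hits += (not a.ambiguous) and a.peptide_site_index == 9
            rates.append(hits / trials)
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]

    def test_trimethyl_never_confused_with_acetyl_when_discriminable(self):
        """When the precursor windows cannot overlap, the acetyl hypothesis
        is rejected at the precursor stage for a trimethylated peptide."""
        from chapmod.masses import discriminable

        pep = "AGKLSADEWR"  # ~1100 Da, well below the ~1819 Da boundary
        spec = _spectrum_for(pep, 3)
        assert discriminable(spec.precursor_neutral_mass, 10.0, "trimethyl", "acetyl")
        localize_site(spec, pep, TRI)  # trimethyl fits
        with pytest.raises(LocalizationError):
            localize_site(spec, pep, get_modification("acetyl"))


class TestMapToProtein:
    def test_offset_arithmetic(self):
        protein = "M" * 311 + "AGKLSAKDEWR" + "M" * 20
        # peptide starts at protein offset 312 (1-based); site 7 -> protein 318
        a = localize_site(_spectrum_for("AGKLSAKDEWR", 7), "AGKLSAKDEWR", TRI)
        mapped = map_to_protein(a, protein, protein="VCPlike")
        assert mapped.protein_site_index == 311 + 7
        assert mapped.label == f"VCPlikeK{311 + 7}"

    def test_peptide_at_origin(self):
        pep = "KAGLSADEWR"
        a = localize_site(_spectrum_for(pep, 1), pep, TRI)
        mapped = map_to_protein(a, pep + "MMMM")
        assert mapped.protein_site_index == 1

    def test_absent_and_duplicate_peptides_error(self):
        pep = "AGKLSADEWR"
        a = localize_site(_spectrum_for(pep, 3), pep, TRI)
        with pytest.raises(MappingError, match="not found"):
            map_to_protein(a, "MMMM")
        with pytest.raises(MappingError, match="candidate protein sites"):
            map_to_protein(a, pep + "GG" + pep)


def test_generator_round_trip_recovers_spiked_sites(small_experiment):
    """Spike -> synthesize spectra -> localize -> map lands on the truth."""
    _, _, truth = small_experiment
    recovered = 0
    for protein, site, mod_name in truth.spiked_sites:
        seq = truth.sequences[protein]
        mod = get_modification(mod_name)
        ok = False
        for spec in spike_modified_peptides(protein, seq, [(site, mod_name)]):
            try:
                a = localize_site(spec, spec.peptide_hint, mod)
                a = map_to_protein(a, seq, protein=protein)
            except (LocalizationError, MappingError):
                continue
            if not a.ambiguous and a.protein_site_index == site:
                ok = True
        recovered += ok
    assert recovered == len(truth.spiked_sites)
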