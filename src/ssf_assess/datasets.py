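"""Bundled example data.

``load_worked_example`` returns the species table and last-period median
lengths-at-catch from a published assessment of three Central African inland
gillnet fisheries (the Kadey River in Cameroon, and small- and large-mesh
gillnet fisheries on the Congo mainstem), together with the published
multispecies catch endpoints.  It is the package's worked example for the
length-based status step and for decline summaries.

Where the published length ratio cannot be reproduced by the empirical
life-history chain (the source used FishBase life-history values not
reprinted in the table), the species table carries a back-derived external
length-at-maturity, reconstructed from the published ratio.  Those values
are synthetic stand-ins, flagged via ``BACK_DERIVED_LM``, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .survey import SpeciesInfo

__all__ = ["WorkedExample", "load_worked_example", "BACK_DERIVED_LM"]

#: species whose external Lm below is back-derived from the published ratio
BACK_DERIVED_LM = {
    "schilbe_mystus": 25.74,
    "hydrocynus_vittatus": 65.22,
    "phenacogrammus_interruptus": 4.90,
    "heterotis_niloticus": 56.60,
    # published row is ambiguous under digit concatenation; Lmax=31/Lc=7 parse
    "brycinus_macrolepidotus": 15.56,
}

# fishery_id, species_id, scientific name, common name, K, M, age_mat, lmax,
# median last-period length-at-catch, published ratio, published label
_ROWS = [
    ("kadey", "distichodus_mossambicus", "Distichodus mossambicus", "Mbengou",
     None, None, None, 57.0, 30.0, 0.92, "overexploited"),
    ("kadey", "distichodus_sp", "Distichodus sp.", "",
     None, None, None, 25.0, None, None, None),
    ("kadey", "hydrocynus_vittatus", "Hydrocynus vittatus", "Ngoki",
     0.34, None, 1.9, 105.0, 45.0, 0.69, "overexploited"),
    ("kadey", "schilbe_mystus", "Schilbe mystus", "Kembo",
     0.21, 0.45, 3.3, 35.0, 17.5, 0.68, "overexploited"),
    ("kadey", "brycinus_macrolepidotus", "Brycinus macrolepidotus", "Longo",
     0.46, 0.98, 1.65, 31.0, 7.0, 0.45, "seriously_overexploited"),
    ("congo_small_mesh", "clarias_gariepinus", "Clarias gariepinus", "Ngolu",
     0.09, 0.2, 6.5, 170.0, 35.0, 0.41, "seriously_overexploited"),
    ("congo_small_mesh", "brycinus_grandisquamis", "Brycinus grandisquamis", "Bakombo",
     0.49, None, 1.5, 26.0, 6.0, 0.37, "seriously_overexploited"),
    ("congo_small_mesh", "citharinus_congicus", "Citharinus congicus", "Ndombolo",
     0.52, 0.9, 1.3, 43.0, 17.5, 0.69, "overexploited"),
    ("congo_small_mesh", "phenacogrammus_interruptus", "Phenacogrammus interruptus", "Tutuko",
     1.87, 3.55, 0.5, 8.5, 5.0, 1.02, "healthy"),
    ("congo_small_mesh", "heterotis_niloticus", "Heterotis niloticus", "Lamer",
     0.19, 0.37, 3.2, 100.0, 30.0, 0.53, "seriously_overexploited"),
    ("congo_large_mesh", "heterotis_niloticus", "Heterotis niloticus", "Lamer",
     0.19, 0.37, 3.2, 100.0, 30.0, 0.53, "seriously_overexploited"),
    ("congo_large_mesh", "citharinus_congicus", "Citharinus congicus", "Ndombolo",
     0.52, 0.9, 1.3, 43.0, 10.0, 0.39, "seriously_overexploited"),
    ("congo_large_mesh", "distichodus_lusosso", "Distichodus lusosso", "Ekese",
     None, 0.79, None, 38.0, 18.0, 0.79, "overexploited"),
    ("congo_large_mesh", "hydrocynus_vittatus", "Hydrocynus vittatus", "Mukobe",
     0.34, None, 1.9, 105.0, 15.0, 0.23, "seriously_overexploited"),
    ("congo_large_mesh", "distichodus_antonii", "Distichodus antonii", "Mboto",
     None, 0.64, None, 55.0, 30.0, 0.95, "overexploited"),
]

#: published multispecies catch endpoints: (first year, first catch kg,
#: last year, last catch kg, published percent decline)
DECLINE_ENDPOINTS = {
    "kadey": (1970, 26.0, 2019, 9.0, 65),
    "congo_large_mesh": (1980, 190.0, 2019, 30.0, 84),
    "congo_small_mesh": (1959, 200.0, 2019, 40.0, 80),
}


@dataclass
class WorkedExample:
    """The worked-example inputs and the published values they should yield."""

    species_obs: pd.DataFrame          # fishery_id, species_id, length_at_catch_cm
    species_table: list[SpeciesInfo]
    published: pd.DataFrame            # fishery_id, species_id, ratio, label
    decline_endpoints: dict[str, tuple]


def load_worked_example() -> WorkedExample:
    """Load the three-fishery worked example (see module docstring)."""
    obs_rows, pub_rows = [], []
    table: dict[str, SpeciesInfo] = {}
    for (fishery, sp, sci, common, k, m, age, lmax, lc, ratio, label) in _ROWS:
        if sp not in table:
            table[sp] = SpeciesInfo(
                species_id=sp, scientific_name=sci, common_name=common,
                lmax_cm=lmax, growth_k=k, natural_mortality_m=m,
                age_at_maturity_yr=age, lm_external_cm=BACK_DERIVED_LM.get(sp))
        if lc is not None:
            obs_rows.append({"fishery_id": fishery, "species_id": sp,
                             "length_at_catch_cm": lc})
        if ratio is not None:
            pub_rows.append({"fishery_id": fishery, "species_id": sp,
                             "ratio": ratio, "label": label})
    return WorkedExample(pd.DataFrame(obs_rows), list(table.values()),
                         pd.DataFrame(pub_rows), dict(DECLINE_ENDPOINTS))
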