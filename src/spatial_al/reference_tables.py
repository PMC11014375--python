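"""Published reference tables from the two crop-mapping study areas.

These small tables summarize the field results the method was developed on:
SA1, a Dutch polder landscape with large regular parcels and seven single
crops, and SA2, a Belgian region with smaller parcels and mostly aggregated
classes. They serve as worked-example inputs for the selection rules and the
report bookkeeping — the package never needs the original imagery.
"""

from __future__ import annotations

from .variogram import VariogramModel

#: Monthly fitted semi-variogram parameters for SA1 (spherical fits; only
#: range in meters and nugget were published, the partial sill is not used
#: by the selection rules and is set to a nominal placeholder).
SA1_MONTHLY_VARIOGRAMS = {
    "January": {"range_m": 462.3, "nugget": 0.008},
    "February": {"range_m": 477.4, "nugget": 0.005},
    "March": {"range_m": 611.2, "nugget": 0.029},
    "April": {"range_m": 513.0, "nugget": 0.029},
    "May": {"range_m": 417.6, "nugget": 0.025},
    "June": {"range_m": 587.3, "nugget": 0.008},
    "July": {"range_m": 905.4, "nugget": 0.043},
    "August": {"range_m": 721.1, "nugget": 0.050},
    "September": {"range_m": 804.9, "nugget": 0.043},
    "October": {"range_m": 733.6, "nugget": 0.033},
    "November": {"range_m": 735.3, "nugget": 0.028},
    "December": {"range_m": 794.0, "nugget": 0.018},
}

#: Minimum distance adopted for SA2 (the SA1 value follows from the table
#: above via select_range).
SA2_RANGE_M = 529.0

#: Per-class training-sample counts in SA1: total pool, spectral-only AL
#: selection, spatially explicit AL selection.
SA1_SELECTION_COUNTS = {
    "Alfalfa": {"total": 50, "spectral_al": 22, "spatial_al": 11},
    "Beets": {"total": 50, "spectral_al": 28, "spatial_al": 16},
    "Cereals": {"total": 50, "spectral_al": 15, "spatial_al": 8},
    "Maize": {"total": 50, "spectral_al": 25, "spatial_al": 15},
    "Onions": {"total": 50, "spectral_al": 23, "spatial_al": 16},
    "Orchard": {"total": 50, "spectral_al": 15, "spatial_al": 7},
    "Potatoes": {"total": 50, "spectral_al": 41, "spatial_al": 24},
}

#: Per-class training-sample counts in SA2.
SA2_SELECTION_COUNTS = {
    "Flax and hemp": {"total": 70, "spectral_al": 25, "spatial_al": 20},
    "Fruits and nuts": {"total": 70, "spectral_al": 40, "spatial_al": 25},
    "Fodder": {"total": 70, "spectral_al": 36, "spatial_al": 25},
    "Grains, seeds, and legumes": {"total": 70, "spectral_al": 32, "spatial_al": 21},
    "Maize": {"total": 70, "spectral_al": 56, "spatial_al": 41},
    "Potatoes": {"total": 70, "spectral_al": 58, "spatial_al": 39},
    "Beets": {"total": 70, "spectral_al": 33, "spatial_al": 30},
    "Vegetables, herbs, and ornamentals": {"total": 70, "spectral_al": 47, "spatial_al": 22},
}


def sa1_monthly_models(partial_sill: float = 0.03) -> list:
    """The SA1 monthly fits as VariogramModel objects (spherical family)."""
    return [
        VariogramModel("spherical", row["nugget"], partial_sill, row["range_m"])
        for row in SA1_MONTHLY_VARIOGRAMS.values()
    ]


def selection_totals(counts: dict) -> dict:
    """Column totals of a per-class selection-count table."""
    keys = ("total", "spectral_al", "spatial_al")
    return {k: sum(row[k] for row in counts.values()) for k in keys}
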