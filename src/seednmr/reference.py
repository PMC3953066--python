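"""Published reference component sets for Arabidopsis seeds.

These are the measured (amplitude %, T2 ms) component tables for wild-type
Col-0 and the mucilage mutants mum2-11 and myb5-1, dry and after 24 h
imbibition, plus wild type imbibed 1 h after removal of water-soluble
mucilage (WSM).  They serve as ground-truth generators for the synthetic
decay module: simulating noiseless FID+CPMG curves from a row and fitting
them back is the package's primary self-check.

Printed amplitudes sum to approximately (not exactly) 100 per row; sets are
renormalized to exactly 100 on construction, which perturbs individual
amplitudes by at most 0.1 % relative except for the wild-type 24 h row whose
printed amplitudes sum to 109.9.
"""

from __future__ import annotations

from .core import ComponentSet

__all__ = ["REFERENCE_SETS", "DRY_LABELS", "IMBIBED_LABELS", "reference_set"]

#: Attribution by ascending T2 rank. In dry seeds components 3 and 4 are pure
#: oil; on imbibition they gain intracellular and adherent-mucilage water
#: respectively, and a fifth pool of external water appears.
DRY_LABELS = ["solid", "exchangeable", "oil_intracellular_water", "oil_mucilage_water"]
IMBIBED_LABELS = DRY_LABELS + ["external_water"]

_ROWS: dict[str, tuple[list[float], list[float], str]] = {
    # name: (amplitudes %, T2 ms, state)
    "wt-wsm-imb-1h": ([12.5, 26.2, 29.6, 31.8], [0.0240, 3.487, 43.9, 223.0], "imbibed"),
    "wt-dry": ([49.1, 11.5, 20.2, 19.2], [0.0164, 0.231, 35.2, 138.0], "dry"),
    "wt-imb-24h": ([10.5, 18.4, 33.0, 38.1, 9.9], [0.0249, 2.466, 19.8, 114.0, 457.0], "imbibed"),
    "mum2-dry": ([45.6, 11.2, 22.1, 21.0], [0.0165, 0.211, 35.2, 140.0], "dry"),
    "mum2-imb-24h": ([14.0, 15.4, 46.5, 20.3, 3.9], [0.0239, 1.068, 11.7, 78.0, 319.0], "imbibed"),
    "myb5-dry": ([42.9, 10.5, 23.9, 22.7], [0.0165, 0.176, 35.8, 141.0], "dry"),
    "myb5-imb-24h": ([11.6, 15.5, 37.3, 29.9, 5.7], [0.0231, 1.212, 13.5, 67.0, 266.0], "imbibed"),
}

#: Per-compartment water content (% of total sample mass) reported alongside
#: the amplitudes, used to parameterize realistic synthetic seeds.
REFERENCE_WATER: dict[str, list[float]] = {
    "wt-wsm-imb-1h": [0.0, 19.0, 10.39, 12.52],
    "wt-dry": [0.0, 8.46, 0.0, 0.0],
    "wt-imb-24h": [0.0, 15.59, 17.29, 22.16, 8.39],
    "mum2-dry": [0.0, 8.5, 0.0, 0.0],
    "mum2-imb-24h": [0.0, 12.30, 21.05, 0.99, 3.09],
    "myb5-dry": [0.0, 8.10, 0.0, 0.0],
    "myb5-imb-24h": [0.0, 12.66, 15.92, 10.67, 4.61],
}


def reference_set(name: str) -> ComponentSet:
    """Return a labelled, normalized reference component set by name.

    Names: 'wt-dry', 'wt-imb-24h', 'wt-wsm-imb-1h', 'mum2-dry',
    'mum2-imb-24h', 'myb5-dry', 'myb5-imb-24h'.
    """
    try:
        amps, t2s, state = _ROWS[name]
    except KeyError:
        raise KeyError(f"unknown reference set {name!r}; choose from {sorted(_ROWS)}") from None
    labels = DRY_LABELS if len(amps) == 4 else IMBIBED_LABELS
    return ComponentSet.from_amplitudes(amps, t2s, labels, state=state)


REFERENCE_SETS: dict[str, ComponentSet] = {name: reference_set(name) for name in _ROWS}
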