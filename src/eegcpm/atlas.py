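"""Cortical parcellation labels.

The Desikan-Killiany atlas divides each hemisphere into 34 cortical
regions, giving 68 regions of interest in total. Only the ordered label
list is shipped here — edge indices throughout the package refer to
positions in this ordering (left hemisphere first).
"""

from __future__ import annotations

_DK_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Ordered 68-label Desikan-Killiany cortical parcellation.
DESIKAN_KILLIANY_68 = tuple(
    f"{hemi}-{region}" for hemi in ("lh", "rh") for region in _DK_REGIONS
)

N_ROIS_DK = len(DESIKAN_KILLIANY_68)


def default_roi_names(n_rois: int) -> tuple[str, ...]:
    """ROI labels for an ``n_rois``-region parcellation.

    Returns the Desikan-Killiany labels when ``n_rois`` is 68, otherwise
    generic ``roi_000``-style labels (used by reduced-scale simulations).
    """
    if n_rois == N_ROIS_DK:
        return DESIKAN_KILLIANY_68
    return tuple(f"roi_{i:03d}" for i in range(n_rois))
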