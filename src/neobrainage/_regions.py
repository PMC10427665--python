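"""Region label schemes.

The default scheme is an 87-entry id -> name lookup mirroring the DRAW-EM
neonatal parcellation (labels 1..87, label 0 = background).  Any label id
not covered by a scheme falls back to ``region_<id>``.
"""

from __future__ import annotations

DRAW_EM_87: dict[int, str] = {
    1: "Hippocampus left",
    2: "Hippocampus right",
    3: "Amygdala left",
    4: "Amygdala right",
    5: "Anterior temporal lobe, medial part left GM",
    6: "Anterior temporal lobe, medial part right GM",
    7: "Anterior temporal lobe, lateral part left GM",
    8: "Anterior temporal lobe, lateral part right GM",
    9: "Gyri parahippocampalis et ambiens anterior part left GM",
    10: "Gyri parahippocampalis et ambiens anterior part right GM",
    11: "Superior temporal gyrus, middle part left GM",
    12: "Superior temporal gyrus, middle part right GM",
    13: "Medial and inferior temporal gyri anterior part left GM",
    14: "Medial and inferior temporal gyri anterior part right GM",
    15: "Lateral occipitotemporal gyrus, gyrus fusiformis anterior part left GM",
    16: "Lateral occipitotemporal gyrus, gyrus fusiformis anterior part right GM",
    17: "Cerebellum left",
    18: "Cerebellum right",
    19: "Brainstem",
    20: "Insula right GM",
    21: "Insula left GM",
    22: "Occipital lobe right GM",
    23: "Occipital lobe left GM",
    24: "Gyri parahippocampalis et ambiens posterior part right GM",
    25: "Gyri parahippocampalis et ambiens posterior part left GM",
    26: "Lateral occipitotemporal gyrus, gyrus fusiformis posterior part right GM",
    27: "Lateral occipitotemporal gyrus, gyrus fusiformis posterior part left GM",
    28: "Medial and inferior temporal gyri posterior part right GM",
    29: "Medial and inferior temporal gyri posterior part left GM",
    30: "Superior temporal gyrus, posterior part right GM",
    31: "Superior temporal gyrus, posterior part left GM",
    32: "Cingulate gyrus, anterior part right GM",
    33: "Cingulate gyrus, anterior part left GM",
    34: "Cingulate gyrus, posterior part right GM",
    35: "Cingulate gyrus, posterior part left GM",
    36: "Frontal lobe right GM",
    37: "Frontal lobe left GM",
    38: "Parietal lobe right GM",
    39: "Parietal lobe left GM",
    40: "Caudate nucleus right",
    41: "Caudate nucleus left",
    42: "Thalamus right, high intensity part",
    43: "Thalamus left, high intensity part",
    44: "Subthalamic nucleus right",
    45: "Subthalamic nucleus left",
    46: "Lentiform nucleus right",
    47: "Lentiform nucleus left",
    48: "Corpus callosum",
    49: "Lateral ventricle left",
    50: "Lateral ventricle right",
    51: "Anterior temporal lobe, medial part left WM",
    52: "Anterior temporal lobe, medial part right WM",
    53: "Anterior temporal lobe, lateral part left WM",
    54: "Anterior temporal lobe, lateral part right WM",
    55: "Gyri parahippocampalis et ambiens anterior part left WM",
    56: "Gyri parahippocampalis et ambiens anterior part right WM",
    57: "Superior temporal gyrus, middle part left WM",
    58: "Superior temporal gyrus, middle part right WM",
    59: "Medial and inferior temporal gyri anterior part left WM",
    60: "Medial and inferior temporal gyri anterior part right WM",
    61: "Lateral occipitotemporal gyrus, gyrus fusiformis anterior part left WM",
    62: "Lateral occipitotemporal gyrus, gyrus fusiformis anterior part right WM",
    63: "Insula right WM",
    64: "Insula left WM",
    65: "Occipital lobe right WM",
    66: "Occipital lobe left WM",
    67: "Gyri parahippocampalis et ambiens posterior part right WM",
    68: "Gyri parahippocampalis et ambiens posterior part left WM",
    69: "Lateral occipitotemporal gyrus, gyrus fusiformis posterior part right WM",
    70: "Lateral occipitotemporal gyrus, gyrus fusiformis posterior part left WM",
    71: "Medial and inferior temporal gyri posterior part right WM",
    72: "Medial and inferior temporal gyri posterior part left WM",
    73: "Superior temporal gyrus, posterior part right WM",
    74: "Superior temporal gyrus, posterior part left WM",
    75: "Cingulate gyrus, anterior part right WM",
    76: "Cingulate gyrus, anterior part left WM",
    77: "Cingulate gyrus, posterior part right WM",
    78: "Cingulate gyrus, posterior part left WM",
    79: "Frontal lobe right WM",
    80: "Frontal lobe left WM",
    81: "Parietal lobe right WM",
    82: "Parietal lobe left WM",
    83: "CSF",
    84: "Extra-cranial background",
    85: "Intracranial background",
    86: "Thalamus right, low intensity part",
    87: "Thalamus left, low intensity part",
}

#: Region ids of the default scheme, in scheme order.
DEFAULT_REGION_IDS: tuple[int, ...] = tuple(sorted(DRAW_EM_87))


def region_name(region_id: int, scheme: dict[int, str] | None = None) -> str:
    """Name for a label id; unknown ids map to ``region_<id>``."""
    lookup = DRAW_EM_87 if scheme is None else scheme
    return lookup.get(int(region_id), f"region_{int(region_id)}")
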