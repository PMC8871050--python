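"""Published region-level reference statistics.

Region-wise results published for a two-group multimodal MRI comparison
(schizophrenia vs. depression, 44 subjects, three modalities: task fMRI,
resting-state fMRI, structural MRI; Neuromorphometrics parcellation).
Each row gives the printed p-value, chi-square statistic (df = 3), and the
three components of the leading canonical vector (CV1 = task fMRI,
CV2 = resting fMRI, CV3 = structural).

These values validate output conventions only — the chi-square-to-p
mapping at df = 3 and the unit-norm reporting of canonical vectors.  They
cannot be recomputed here because the underlying subject-level images were
not published; canonical-vector signs are arbitrary.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["PublishedRegionStat", "PUBLISHED_REGION_STATS", "PUBLISHED_DF"]

PUBLISHED_DF = 3  # 3 modalities x 1 group contrast


class PublishedRegionStat(NamedTuple):
    region: str
    p_value: float
    chi_square: float
    cv: tuple[float, float, float]


PUBLISHED_REGION_STATS: list[PublishedRegionStat] = [
    PublishedRegionStat("Left planum polare", 0.0008, 16.7299, (0.6319, 0.7613, -0.1453)),
    PublishedRegionStat("Left opercular part of the inferior frontal gyrus", 0.0022, 14.5809, (-0.4026, -0.8402, 0.3633)),
    PublishedRegionStat("Left medial orbital gyrus", 0.0039, 13.3569, (-0.2124, -0.9564, 0.2005)),
    PublishedRegionStat("Left posterior insula", 0.0077, 11.9015, (-0.3233, -0.9339, 0.1530)),
    PublishedRegionStat("Left parahippocampal gyrus", 0.0092, 11.5353, (-0.3229, -0.9040, 0.2800)),
    PublishedRegionStat("Right lateral orbital gyrus", 0.0121, 10.9252, (0.2551, 0.8937, -0.3690)),
    PublishedRegionStat("Right supramarginal gyrus", 0.0134, 10.7141, (0.0964, -0.6804, 0.7265)),
    PublishedRegionStat("Right anterior orbital gyrus", 0.0169, 10.2093, (0.1428, -0.7306, 0.6677)),
    PublishedRegionStat("Right supplementary motor cortex", 0.0197, 9.8746, (-0.0688, -0.7482, 0.6599)),
    PublishedRegionStat("Left supplementary motor cortex", 0.0203, 9.8031, (-0.0859, 0.7082, -0.7007)),
    PublishedRegionStat("Left superior temporal gyrus", 0.0208, 9.7535, (-0.2775, -0.8334, 0.4779)),
    PublishedRegionStat("Left temporal pole", 0.0211, 9.7250, (0.3911, 0.8486, -0.3563)),
    PublishedRegionStat("Left anterior orbital gyrus", 0.0238, 9.4530, (-0.1262, 0.7232, -0.6790)),
    PublishedRegionStat("Right middle frontal gyrus", 0.0243, 9.4139, (0.3836, -0.4898, 0.7829)),
    PublishedRegionStat("Left Amygdala", 0.0263, 9.2404, (-0.2334, -0.9612, 0.1474)),
    PublishedRegionStat("Left frontal operculum", 0.0267, 9.2025, (0.2479, 0.9685, 0.0226)),
    PublishedRegionStat("Right angular gyrus", 0.0274, 9.1444, (0.0716, -0.7811, 0.6202)),
    PublishedRegionStat("Right middle temporal gyrus", 0.0277, 9.1216, (0.2095, -0.9312, 0.2982)),
    PublishedRegionStat("Left superior frontal gyrus medial segment", 0.0285, 9.0578, (0.0298, -0.7775, 0.6282)),
    PublishedRegionStat("Left superior parietal lobule", 0.0305, 8.9095, (0.4082, -0.4644, 0.7859)),
    PublishedRegionStat("Left Hippocampus", 0.0307, 8.9001, (-0.2239, -0.9630, 0.1502)),
    PublishedRegionStat("Right superior temporal gyrus", 0.0332, 8.7205, (0.1746, -0.8503, 0.4964)),
    PublishedRegionStat("Right posterior insula", 0.0341, 8.6677, (-0.0524, -0.9878, 0.1469)),
    PublishedRegionStat("Left central operculum", 0.0348, 8.6178, (-0.2178, -0.9620, 0.1649)),
    PublishedRegionStat("Left fusiform gyrus", 0.0350, 8.6045, (-0.4066, -0.8550, 0.3219)),
    PublishedRegionStat("Left middle cingulate gyrus", 0.0351, 8.5999, (-0.1485, -0.9698, 0.1935)),
    PublishedRegionStat("Left medial frontal cortex", 0.0366, 8.5070, (0.0482, -0.9819, 0.1833)),
    PublishedRegionStat("Right parietal operculum", 0.0378, 8.4347, (-0.0461, -0.9966, 0.0686)),
    PublishedRegionStat("Right middle cingulate gyrus", 0.0388, 8.3761, (-0.2403, -0.9456, 0.2196)),
    PublishedRegionStat("Left middle frontal gyrus", 0.0395, 8.3418, (0.2894, -0.5013, 0.8154)),
    PublishedRegionStat("Left gyrus rectus", 0.0403, 8.2928, (-0.3306, -0.8902, 0.3133)),
    PublishedRegionStat("Left entorhinal area", 0.0406, 8.2803, (-0.7626, -0.5786, 0.2894)),
    PublishedRegionStat("Left posterior cingulate gyrus", 0.0441, 8.0939, (-0.2762, -0.9312, 0.2378)),
    PublishedRegionStat("Left middle temporal gyrus", 0.0451, 8.0429, (-0.0043, -0.9256, 0.3785)),
    PublishedRegionStat("Right superior frontal gyrus", 0.0453, 8.0345, (0.6047, -0.3385, 0.7209)),
    PublishedRegionStat("Left anterior cingulate gyrus", 0.0471, 7.9465, (-0.1187, -0.8082, 0.5768)),
    PublishedRegionStat("Right anterior cingulate gyrus", 0.0493, 7.8452, (-0.0797, -0.6843, 0.7249)),
    PublishedRegionStat("Right medial orbital gyrus", 0.0501, 7.8105, (-0.0785, -0.9286, 0.3626)),
    PublishedRegionStat("Left Basal Forebrain", 0.0508, 7.7787, (-0.6022, -0.7983, 0.0046)),
    PublishedRegionStat("Right gyrus rectus", 0.0513, 7.7589, (-0.4299, -0.8586, 0.2792)),
    PublishedRegionStat("Right superior frontal gyrus medial segment", 0.0521, 7.7212, (0.1002, -0.7965, 0.5963)),
    PublishedRegionStat("Right central operculum", 0.0526, 7.7016, (-0.0305, -0.9853, 0.1684)),
    PublishedRegionStat("Right medial frontal cortex", 0.0544, 7.6275, (0.0393, 0.9953, 0.0889)),
]
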