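"""Canonical feature registry: 55 names, partitioned by family.

The partition is 1 size + 8 first-order + 15 GLCM + 13 GLRLM + 13 GLSZM +
5 NGTDM. The size feature is named ``Volume`` in both 2D and 3D analyses
(in 2D it holds the slice area in mm^2).
"""

from __future__ import annotations

SIZE_FEATURES = ("Volume",)

FIRST_ORDER_FEATURES = (
    "Int_Mean",
    "Int_Median",
    "Int_StdDev",
    "Int_Skewness",
    "Int_Kurtosis",
    "Int_Energy",
    "Int_Entropy",
    "Int_Uniformity",
)

GLCM_FEATURES = (
    "GLCM_Energy",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_SumAverage",
    "GLCM_SumVariance",
    "GLCM_SumEntropy",
    "GLCM_Entropy",
    "GLCM_DifferenceVariance",
    "GLCM_DifferenceEntropy",
    "GLCM_InverseDifferenceMoment",
    "GLCM_Autocorrelation",
    "GLCM_ClusterShade",
    "GLCM_ClusterProminence",
    "GLCM_Dissimilarity",
    "GLCM_MaximumProbability",
)

GLRLM_FEATURES = (
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_GLN",
    "GLRLM_RLN",
    "GLRLM_RunPercentage",
    "GLRLM_LGLRE",
    "GLRLM_HGLRE",
    "GLRLM_SRLGLE",
    "GLRLM_SRHGLE",
    "GLRLM_LRLGLE",
    "GLRLM_LRHGLE",
    "GLRLM_GrayLevelVariance",
    "GLRLM_RunLengthVariance",
)

GLSZM_FEATURES = (
    "GLSZM_SAE",
    "GLSZM_LAE",
    "GLSZM_GLN",
    "GLSZM_ZSN",
    "GLSZM_ZonePercentage",
    "GLSZM_LGLZE",
    "GLSZM_HGLZE",
    "GLSZM_SALGLE",
    "GLSZM_SAHGLE",
    "GLSZM_LZLGLE",
    "GLSZM_LZHGLE",
    "GLSZM_GrayLevelVariance",
    "GLSZM_ZoneSizeVariance",
)

NGTDM_FEATURES = (
    "NGTDM_Coarseness",
    "NGTDM_Contrast",
    "NGTDM_Busyness",
    "NGTDM_Complexity",
    "NGTDM_Strength",
)

FAMILIES: dict[str, tuple[str, ...]] = {
    "size": SIZE_FEATURES,
    "first_order": FIRST_ORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

ALL_FEATURES: tuple[str, ...] = (
    SIZE_FEATURES
    + FIRST_ORDER_FEATURES
    + GLCM_FEATURES
    + GLRLM_FEATURES
    + GLSZM_FEATURES
    + NGTDM_FEATURES
)

N_FEATURES = len(ALL_FEATURES)
assert N_FEATURES == 55
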