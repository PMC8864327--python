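"""Published summary operating points for the five caries-detection technologies.

These are the printed summary sensitivity/specificity points with 95%
credible intervals from the source comparative evidence synthesis: the
fully within-person analysis (19 studies, 3 technologies) and the network
meta-analysis (64 studies, 5 technologies).  They serve as reference inputs
for worked examples and consequence tables; the package does not need them
to fit anything.

Known print issues in the source tables are documented in docs/methods.md
and are not reproduced here.
"""

#: Fully within-person analysis (M3): summary points and 95% CrIs.
WITHIN_PERSON_SUMMARY = {
    "fluorescence": {"se": 0.71, "se_cri": (0.59, 0.81), "sp": 0.88, "sp_cri": (0.78, 0.94)},
    "imaging": {"se": 0.48, "se_cri": (0.35, 0.62), "sp": 0.92, "sp_cri": (0.84, 0.96)},
    "visual": {"se": 0.82, "se_cri": (0.73, 0.89), "sp": 0.85, "sp_cri": (0.74, 0.93)},
}

#: Network meta-analysis (M2-NMA): summary points and 95% CrIs, all 5
#: technologies.
NMA_SUMMARY = {
    "visual": {"se": 0.83, "se_cri": (0.77, 0.87), "sp": 0.81, "sp_cri": (0.73, 0.87)},
    "fluorescence": {"se": 0.76, "se_cri": (0.68, 0.82), "sp": 0.83, "sp_cri": (0.75, 0.89)},
    "imaging": {"se": 0.50, "se_cri": (0.40, 0.59), "sp": 0.89, "sp_cri": (0.83, 0.93)},
    "electrical": {"se": 0.83, "se_cri": (0.66, 0.92), "sp": 0.72, "sp_cri": (0.44, 0.89)},
    "transillumination_oct": {"se": 0.76, "se_cri": (0.63, 0.86), "sp": 0.82, "sp_cri": (0.68, 0.91)},
}

#: Prevalence of the illustrative per-1,000 consequence tables (coronal
#: dentine caries prevalence from a national adult dental health survey).
ILLUSTRATIVE_PREVALENCE = 0.28
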