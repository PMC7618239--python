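"""Reference cohort bookkeeping for the developmental SST+ dataset.

Post-QC cell counts per developmental stage of the FACS-sorted cortical
SST+ scRNA-seq cohort this pipeline was designed around, used for
documentation consistency checks and for sizing synthetic cohorts.
"""

REFERENCE_STAGE_CELL_COUNTS = {"E16.5": 3841, "P1": 2418, "P5": 2895}
REFERENCE_TOTAL_CELLS = 9154

# fixed-cell FACS P5 cohort used for cross-dataset alignment
REFERENCE_FIXED_P5_CELLS = 11477
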