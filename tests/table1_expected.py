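"""Published status codes of the 25-patient reference cohort.

Hand-transcribed from the source series' patient table: per patient the
printed MRI, PET, OS and PFS status cells (1 = responder,
0 = non-responder, None = not available).  Used as the regression
oracle for the classification rules; the pipeline never reads these —
it recomputes every status from the measurements.
"""

# patient_id: (mri, pet, os, pfs)
TABLE1_STATUS = {
    1: (0, None, 1, 1),
    2: (0, 0, 0, 1),
    3: (None, 0, 0, 0),
    4: (1, 1, 1, 1),
    5: (1, 0, 0, 0),
    6: (0, 0, 1, 1),
    7: (1, 1, 1, 1),
    8: (1, 0, 1, 1),
    9: (0, 0, 0, 0),
    10: (1, 1, 1, 0),
    11: (1, 0, 0, 0),
    12: (1, 1, 1, 1),
    13: (None, 0, 0, 0),
    14: (1, 1, 1, 0),
    15: (None, 1, 1, 1),
    16: (1, 1, 1, 0),
    17: (1, 1, 1, 1),
    18: (0, 0, 0, 1),
    19: (0, 1, 1, 1),
    20: (1, 0, 0, 1),
    21: (1, 0, 0, 0),
    22: (1, 0, 1, 0),
    23: (0, 0, 1, 1),
    24: (None, None, 0, 0),
    25: (1, 1, 1, 1),
}
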