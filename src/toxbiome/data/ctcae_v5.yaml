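# Hematologic adverse-event grading thresholds (CTCAE v5.0 laboratory bands).
#
# Units: 10^9 cells/L for leukocyte, neutrophil, lymphocyte and platelet
# counts; g/L for hemoglobin.  Each band is [lower, upper) on the analyte
# value; lower values are worse for every hematologic AE.  Bands must be
# contiguous and cover (0, inf).
#
# CTCAE v5.0 defines grade 4 anemia clinically ("life-threatening") rather
# than by a hemoglobin cutoff; the 65 g/L bound below is an editable
# convention so that grading stays a pure function of the lab value.
# The grade-1 lower bounds are the local lower limits of normal (LLN).
leukopenia:
  analyte: wbc
  direction: low
  bands:  # [lower, upper, grade]
    - [4.0, .inf, 0]
    - [3.0, 4.0, 1]
    - [2.0, 3.0, 2]
    - [1.0, 2.0, 3]
    - [0.0, 1.0, 4]
neutropenia:
  analyte: anc
  direction: low
  bands:
    - [2.0, .inf, 0]
    - [1.5, 2.0, 1]
    - [1.0, 1.5, 2]
    - [0.5, 1.0, 3]
    - [0.0, 0.5, 4]
lymphopenia:
  analyte: alc
  direction: low
  bands:
    - [1.0, .inf, 0]
    - [0.8, 1.0, 1]
    - [0.5, 0.8, 2]
    - [0.2, 0.5, 3]
    - [0.0, 0.2, 4]
anemia:
  analyte: hgb
  direction: low
  bands:
    - [110.0, .inf, 0]
    - [100.0, 110.0, 1]
    - [80.0, 100.0, 2]
    - [65.0, 80.0, 3]
    - [0.0, 65.0, 4]
thrombocytopenia:
  analyte: plt
  direction: low
  bands:
    - [125.0, .inf, 0]
    - [75.0, 125.0, 1]
    - [50.0, 75.0, 2]
    - [25.0, 50.0, 3]
    - [0.0, 25.0, 4]
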