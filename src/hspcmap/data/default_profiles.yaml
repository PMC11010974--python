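# Default synthetic population profiles and cohort mixtures.
#
# All intensities are raw fluorescence (arbitrary units, linear detector
# scale); `cv` is the coefficient of variation of the per-marker log-normal.
# Positivity calls refer to the generator's own raw positivity cutoff of 300
# a.u. (CD123 "low" band: 300-2000 a.u.). Scatter channels are log-normal as
# well; FSC-H tracks FSC-A up to a small ratio jitter on singlets.
#
# The HSPC profiles realize the canonical CD34/CD38/CD45RA/CD123 antigen
# combinations (HSC/MPP, CLP, CMP, MEP, GMP). LEUK_BLAST is a leukemia-like
# population: CD34 dim, strong CD45RA/CD123 co-expression and high PD-L1.
# LYMPHOCYTE / MONOCYTE / GRANULOCYTE are CD34-negative background
# populations present so that the scatter / CD45 / GOI gating steps have
# something to remove.

markers: [CD34, CD38, CD45RA, CD123, PD-L1]

profiles:
  HSC_MPP:
    positivity: {CD34: "+", CD38: "-", CD45RA: "-", CD123: "-", PD-L1: "-"}
    means: {CD34: 5000, CD38: 50, CD45RA: 60, CD123: 60, PD-L1: 120,
            CD45: 1500, VIABILITY: 80, FSC: 60000, SSC: 25000}
    cvs:   {CD34: 0.40, CD38: 0.60, CD45RA: 0.60, CD123: 0.60, PD-L1: 0.50,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  CLP:
    positivity: {CD34: "+", CD38: "-", CD45RA: "+", CD123: "-", PD-L1: "-"}
    means: {CD34: 4000, CD38: 70, CD45RA: 4000, CD123: 70, PD-L1: 130,
            CD45: 1800, VIABILITY: 80, FSC: 55000, SSC: 22000}
    cvs:   {CD34: 0.40, CD38: 0.60, CD45RA: 0.45, CD123: 0.60, PD-L1: 0.50,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  CMP:
    positivity: {CD34: "+", CD38: "+", CD45RA: "-", CD123: "low", PD-L1: "-"}
    means: {CD34: 3500, CD38: 5000, CD45RA: 70, CD123: 800, PD-L1: 150,
            CD45: 1600, VIABILITY: 80, FSC: 62000, SSC: 28000}
    cvs:   {CD34: 0.40, CD38: 0.40, CD45RA: 0.60, CD123: 0.35, PD-L1: 0.50,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  MEP:
    positivity: {CD34: "+", CD38: "+", CD45RA: "-", CD123: "-", PD-L1: "-"}
    means: {CD34: 3500, CD38: 5500, CD45RA: 55, CD123: 55, PD-L1: 110,
            CD45: 1500, VIABILITY: 80, FSC: 60000, SSC: 26000}
    cvs:   {CD34: 0.40, CD38: 0.40, CD45RA: 0.60, CD123: 0.60, PD-L1: 0.50,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  GMP:
    positivity: {CD34: "+", CD38: "+", CD45RA: "+", CD123: "+", PD-L1: "-"}
    means: {CD34: 3000, CD38: 6000, CD45RA: 3800, CD123: 3500, PD-L1: 200,
            CD45: 1700, VIABILITY: 80, FSC: 64000, SSC: 30000}
    cvs:   {CD34: 0.40, CD38: 0.40, CD45RA: 0.45, CD123: 0.40, PD-L1: 0.50,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  LEUK_BLAST:
    positivity: {CD34: "+", CD38: "+", CD45RA: "+", CD123: "+", PD-L1: "+"}
    means: {CD34: 1800, CD38: 2500, CD45RA: 9000, CD123: 9000, PD-L1: 3500,
            CD45: 1200, VIABILITY: 80, FSC: 65000, SSC: 24000}
    cvs:   {CD34: 0.35, CD38: 0.50, CD45RA: 0.30, CD123: 0.30, PD-L1: 0.35,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  OTHER:
    positivity: {CD34: "+", CD38: "+", CD45RA: "+", CD123: "-", PD-L1: "-"}
    means: {CD34: 2500, CD38: 4500, CD45RA: 3500, CD123: 80, PD-L1: 150,
            CD45: 1600, VIABILITY: 80, FSC: 60000, SSC: 27000}
    cvs:   {CD34: 0.40, CD38: 0.40, CD45RA: 0.45, CD123: 0.60, PD-L1: 0.50,
            CD45: 0.40, VIABILITY: 0.50, FSC: 0.12, SSC: 0.20}
  LYMPHOCYTE:
    positivity: {CD34: "-", CD38: "+", CD45RA: "+", CD123: "-", PD-L1: "-"}
    means: {CD34: 30, CD38: 1500, CD45RA: 3000, CD123: 60, PD-L1: 90,
            CD45: 8000, VIABILITY: 80, FSC: 48000, SSC: 15000}
    cvs:   {CD34: 0.60, CD38: 0.60, CD45RA: 0.50, CD123: 0.60, PD-L1: 0.50,
            CD45: 0.30, VIABILITY: 0.50, FSC: 0.10, SSC: 0.15}
  MONOCYTE:
    positivity: {CD34: "-", CD38: "+", CD45RA: "-", CD123: "low", PD-L1: "+"}
    means: {CD34: 35, CD38: 3000, CD45RA: 200, CD123: 1500, PD-L1: 1200,
            CD45: 6000, VIABILITY: 80, FSC: 80000, SSC: 50000}
    cvs:   {CD34: 0.60, CD38: 0.50, CD45RA: 0.60, CD123: 0.50, PD-L1: 0.50,
            CD45: 0.30, VIABILITY: 0.50, FSC: 0.12, SSC: 0.18}
  GRANULOCYTE:
    positivity: {CD34: "-", CD38: "+", CD45RA: "-", CD123: "-", PD-L1: "-"}
    means: {CD34: 30, CD38: 1500, CD45RA: 200, CD123: 150, PD-L1: 200,
            CD45: 3000, VIABILITY: 80, FSC: 90000, SSC: 130000}
    cvs:   {CD34: 0.60, CD38: 0.60, CD45RA: 0.60, CD123: 0.60, PD-L1: 0.50,
            CD45: 0.30, VIABILITY: 0.50, FSC: 0.12, SSC: 0.15}

# Whole-sample mixtures (fractions of all acquired WBC events). The CD34+
# compartment of the CR mixture follows the remission composition
# (HSC/MPP 0.7%, CLP 1.2%, CMP 9.4%, MEP 11.4%, GMP 44.6%, Other 32.7% of
# CD34+ cells, here 40% of events); the AD mixture is blast-enriched:
# more CD38- HSC/MPP, more CLP, and a CD45RA+/CD123+/PD-L1-high
# leukemic-blast population absent from remission marrow.
mixtures:
  CR:
    LYMPHOCYTE: 0.30
    MONOCYTE: 0.10
    GRANULOCYTE: 0.20
    HSC_MPP: 0.0028
    CLP: 0.0048
    CMP: 0.0376
    MEP: 0.0456
    GMP: 0.1784
    OTHER: 0.1308
  AD:
    LYMPHOCYTE: 0.20
    MONOCYTE: 0.08
    GRANULOCYTE: 0.17
    HSC_MPP: 0.0770
    CLP: 0.0220
    CMP: 0.0275
    MEP: 0.0495
    GMP: 0.1650
    LEUK_BLAST: 0.1650
    OTHER: 0.0440
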