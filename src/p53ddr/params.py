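"""Packaged default parameter set for the DDR model.

``DEFAULT_PARAMS`` is a synthetic, calibrated-like parameter set: it was
chosen so that simulations from steady state under effective cisplatin
stress reproduce the qualitative phenotype of the HepG2 reporter data the
model was designed for — a sustained total-p53 rise peaking around 30-40
hours (later at higher dose), target proteins (MDM2, p21, BTG2) peaking
hours later than p53, near-complete stress decay within three days, and
positive steady-state co-variation of p53 and MDM2 under changes in
feedback strength.  It is not a fit to any experimental dataset; it is the
ground truth for the synthetic-data generators and the base set for
virtual-cohort studies.
"""

from p53ddr.model import KineticParameters, ObservableMap

__all__ = ["DEFAULT_PARAMS", "DEFAULT_OBSERVABLE_MAP"]

DEFAULT_PARAMS = KineticParameters(
    # DNA damage: constitutive occurrence, p53-p-stimulated repair
    ks_DD=0.1,
    kd_DD=0.06,
    # effective cisplatin stress: decay rate and dose amplitudes
    tau=0.04,
    EC1=1.0,
    EC2=2.2,
    EC3=4.0,
    # p53 mRNA (decoupled from damage) and protein turnover
    ks_p53_RNA=0.1,
    kd_p53_RNA=0.1,
    ks_p53=0.1,
    kd_p53=0.02,
    # phosphorylation cycle; phosphorylation protects p53 from MDM2, so the
    # MDM2-dependent rate for p53-p is much smaller than for p53
    kp=0.5,
    kdp=0.1,
    kd_p53p=0.01,
    kd_p53_mdm2=1.0,
    kd_p53p_mdm2=0.012,
    # MDM2 branch: transcription is almost fully p53-p-dependent (near-zero
    # basal rate), keeping the TP53->MDM2 coupling alive across mechanism
    # scans; slow protein turnover delays the feedback, setting the ~30 h
    # p53 peak
    ks_mdm2_RNA=1e-5,
    ks_mdm2_p53p=0.3,
    Km_mdm2=1.5,
    kd_mdm2_RNA=0.05,
    ks_mdm2=0.01634,
    kd_mdm2=0.02,
    # p21 branch
    ks_p21_RNA=0.02,
    ks_p21_p53p=0.3,
    Km_p21=1.2,
    kd_p21_RNA=0.1,
    ks_p21=0.25,
    kd_p21=0.05,
    # BTG2 branch
    ks_btg2_RNA=0.02,
    ks_btg2_p53p=0.3,
    Km_btg2=1.0,
    kd_btg2_RNA=0.08,
    ks_btg2=0.2,
    kd_btg2=0.045,
    hill_n=4,
)

#: Observable map paired with :data:`DEFAULT_PARAMS` for synthetic GFP data.
DEFAULT_OBSERVABLE_MAP = ObservableMap(
    scaling={"p53": 0.12, "mdm2": 0.25, "p21": 0.3, "btg2": 0.35},
    offset={"p53": 0.02, "mdm2": 0.03, "p21": 0.02, "btg2": 0.03},
)
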