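# Per-family parameters of the statistical potentials, as selected by the
# grid search over contact database, specificity, Taylor completion,
# binning, radius and top-sequence threshold.  "general" is the
# all-families potential.  The C2H2-ZF row keeps the parameters of the
# dedicated zinc-finger potential of earlier work.
families:
  general:
    contacts_db: pbm
    specificity: general
    taylor: true
    binning: acc
    radius: 15
    threshold: 0.82
  AP2:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 15, threshold: 0.88}
  C2H2-ZF:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 30, threshold: 0.94}
  DM:
    {contacts_db: pbm, specificity: family, taylor: true, binning: acc, radius: 22, threshold: 0.92}
  E2F:
    {contacts_db: pbm, specificity: family, taylor: true, binning: acc, radius: 30, threshold: 0.84}
  Ets:
    {contacts_db: pbm, specificity: family, taylor: false, binning: bins, radius: 30, threshold: 0.72}
  Forkhead:
    {contacts_db: pdb, specificity: family, taylor: true, binning: acc, radius: 22, threshold: 0.84}
  GATA:
    {contacts_db: pbm, specificity: general, taylor: false, binning: acc, radius: 15, threshold: 0.92}
  Homeodomain:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 22, threshold: 0.84}
  IRF:
    {contacts_db: pbm, specificity: family, taylor: false, binning: bins, radius: 22, threshold: 0.88}
  Myb/SANT:
    {contacts_db: pdb, specificity: family, taylor: true, binning: acc, radius: 22, threshold: 0.8}
  NAC/NAM:
    {contacts_db: pdb, specificity: family, taylor: false, binning: acc, radius: 15, threshold: 0.76}
  Nuclear receptor:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 22, threshold: 0.96}
  Sox:
    {contacts_db: pdb, specificity: family, taylor: true, binning: bins, radius: 22, threshold: 0.76}
  T-box:
    {contacts_db: pbm, specificity: family, taylor: true, binning: acc, radius: 15, threshold: 0.8}
  WRKY:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 22, threshold: 0.82}
  Zinc cluster:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 15, threshold: 0.82}
  bHLH:
    {contacts_db: pbm, specificity: family, taylor: false, binning: acc, radius: 30, threshold: 0.96}
  bZIP:
    {contacts_db: pdb, specificity: family, taylor: true, binning: acc, radius: 30, threshold: 0.88}
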