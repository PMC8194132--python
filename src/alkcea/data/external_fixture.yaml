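# EXTERNAL-FIXTURE PLACEHOLDERS -- synthetic stand-ins, clearly labelled.
#
# The publication this model re-implements sourced first-line survival
# medians from the named pivotal trials and monthly acquisition costs from
# Spanish list prices (with RD 08/2010 deductions), and defined the
# second-line table in a supplementary file; none of those numbers are
# printed in the article itself.  The values below are placeholders of
# realistic magnitude (medians from the public trial reports where
# available, costs rounded to plausible Spanish monthly acquisition costs).
# Substitute real values here for a production analysis.  Package tests
# depend on these values only through structural properties, never through
# their specific magnitudes.
#
# medians in months; costs in EUR per monthly cycle; admin cost per IV visit.

treatments:
  alectinib:
    molecular_group: ALK
    median_pfs: 34.8          # ALEX update
    median_os: 72.0           # placeholder: OS median not reached in ALEX
    monthly_drug_cost_pfs: 5200.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_alk_tki
  crizotinib_alk:
    molecular_group: ALK
    median_pfs: 10.9          # ALEX comparator arm
    median_os: 57.4
    monthly_drug_cost_pfs: 4950.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_alk_tki
  erlotinib:
    molecular_group: EGFR
    median_pfs: 10.2          # FLAURA comparator class
    median_os: 31.8
    monthly_drug_cost_pfs: 1900.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_egfr_tki
  gefitinib:
    molecular_group: EGFR
    median_pfs: 10.2
    median_os: 31.8
    monthly_drug_cost_pfs: 1150.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_egfr_tki
  afatinib:
    molecular_group: EGFR
    median_pfs: 11.0
    median_os: 31.8
    monthly_drug_cost_pfs: 1950.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_egfr_tki
  osimertinib:
    molecular_group: EGFR
    median_pfs: 18.9          # FLAURA
    median_os: 38.6
    monthly_drug_cost_pfs: 5400.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_egfr_tki
  crizotinib_ros1:
    molecular_group: ROS1
    median_pfs: 19.3          # PROFILE 1001
    median_os: 51.4
    monthly_drug_cost_pfs: 4950.0
    iv_administrations_per_cycle: 0.0
    admin_unit_cost: 211.0
    second_line_link: post_alk_tki
  pembrolizumab:
    molecular_group: WT_TPS_HIGH
    median_pfs: 10.3          # KEYNOTE-024
    median_os: 26.3
    monthly_drug_cost_pfs: 7300.0
    iv_administrations_per_cycle: 1.0
    admin_unit_cost: 211.0
    second_line_link: post_io
  cis_pem:
    molecular_group: WT_TPS_LOW
    median_pfs: 6.9           # PARAMOUNT (induction + maintenance)
    median_os: 13.9
    monthly_drug_cost_pfs: 1750.0
    iv_administrations_per_cycle: 1.0
    admin_unit_cost: 211.0
    second_line_link: post_chemo
    bsa_scaled_fraction: 0.90
  carb_pac_bev:
    molecular_group: WT_TPS_LOW
    median_pfs: 6.2           # Sandler (ECOG 4599)
    median_os: 12.3
    monthly_drug_cost_pfs: 2600.0
    iv_administrations_per_cycle: 1.0
    admin_unit_cost: 211.0
    second_line_link: post_chemo
    bsa_scaled_fraction: 0.55
    weight_scaled_fraction: 0.35
  cis_pem_pembro:
    molecular_group: WT_TPS_LOW
    median_pfs: 8.8           # KEYNOTE-189
    median_os: 22.0
    monthly_drug_cost_pfs: 8200.0
    iv_administrations_per_cycle: 1.0
    admin_unit_cost: 211.0
    second_line_link: post_chemo
    bsa_scaled_fraction: 0.30

# Second-line table (stand-in for the supplementary definition file):
# share of progressing patients who get an active second line (remainder
# best supportive care), its median PFS, and monthly cost; entered in the
# model as a one-off cost at progression.
second_line:
  post_alk_tki:
    share_active_treatment: 0.70
    median_pfs_2l: 5.4
    monthly_drug_cost: 2100.0
    admin_unit_cost: 211.0
  post_egfr_tki:
    share_active_treatment: 0.70
    median_pfs_2l: 4.4
    monthly_drug_cost: 2100.0
    admin_unit_cost: 211.0
  post_chemo:
    share_active_treatment: 0.55
    median_pfs_2l: 4.0
    monthly_drug_cost: 2400.0
    admin_unit_cost: 211.0
  post_io:
    share_active_treatment: 0.60
    median_pfs_2l: 4.5
    monthly_drug_cost: 1500.0
    admin_unit_cost: 211.0
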