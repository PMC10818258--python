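# Default dashboard curation.
#
# The pathway-class and GO-term selections that shape a production
# dashboard are organism- and database-specific, so the defaults here are
# deliberately permissive: every child class of the four metabolic roots
# is shown explicitly (no "Other" buckets) down to the flatten depth, and
# no GO panels are predefined (GO ids live in the PGDB file; list the ones
# you curate under go_panels).  Activity-tag subsystems need no ids and
# are enabled by default.

flatten_depth: 3

# parent class id -> ordered list of child class ids to show explicitly;
# children absent from the list collapse into an "Other <parent>" bucket.
curated_classes: {}

# panel name -> group name -> list of GO term ids (descendants roll up).
go_panels: {}

# panel name -> activity tags drawn from gene annotations.
activity_panels:
  Cell-Exterior: [transporter]
  Central-Dogma: [regulator]

# full subsystem name -> short plot label (otherwise first-letter initials)
abbreviations: {}

# pathway / class / GO ids to remove from the tree
exclude_nodes: []
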