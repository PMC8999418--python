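# Seed localization-group file template (synthetic placeholder entries).
# Format: gene<TAB>group, with groups 1=RPE, 2=outer segment,
# 3=connecting cilium, 4=nucleus in the retinal preset.
# Replace the rows below with the curated seed assignment from your
# literature source (e.g. the ~30-gene retinal localization set).
gene	group
RPE65	1
RHO	2
GNAT1	2
RPGR	3
PRPF31	4
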