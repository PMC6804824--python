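# Default aroma-group decision list.  Rules are evaluated in order; the first
# rule whose clauses all hold assigns the group.  Fields: the five odor-class
# percentages (herbal, fruity, cool, floral, spicy), "total" (ug/g), and
# "+"-joined sums of classes.  Thresholds are a best-effort fit to published
# six-group cultivar classifications and are meant to be edited.
schema_version: 1
rules:
  - label: faint
    all:
      - [total, lt, 1.0]
  - label: cool
    all:
      - [cool, ge, 40.0]
      - [fruity, lt, 20.0]
  - label: musky
    all:
      - [cool, ge, 20.0]
      - [cool+fruity, ge, 55.0]
  - label: lily
    all:
      - [herbal, ge, 20.0]
      - [fruity, ge, 35.0]
  - label: fruity
    all:
      - [fruity, ge, 55.0]
      - [cool, lt, 5.0]
  - label: fruity-honey
    all:
      - [fruity, ge, 40.0]
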