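# Name-matching rules for the 11 mu-opioid receptor agonists approved in Japan.
#
# A verbatim FAERS drugname receives a label iff some include pattern is a
# case-insensitive substring of it and no exclude pattern is.  Substring
# matching deliberately picks up salt/hydrate suffixes (SULFATE, HYDROCHLORIDE,
# HCL, TARTRATE, ...) and combination-product strings.
#
# Exclusion notes:
#   - morphine must not fire on APOMORPHINE (a dopamine agonist).
#     HYDROMORPHONE needs no veto: "MORPHONE" != "MORPHINE" as a substring.
#   - codeine must not fire on DIHYDROCODEINE, which has its own rule.
#   - fentanyl excludes REMIFENTANIL per the extraction convention; note that
#     remifentanil, alfentanil, sufentanil and carfentanil are spelled with
#     "FENTANIL", not "FENTANYL", so only the explicit veto is load-bearing
#     for unusual hybrid strings.
#   - pethidine is listed in FAERS under its US name MEPERIDINE as well.
rules:
  - label: morphine
    include: [MORPHINE]
    exclude: [APOMORPHINE]
  - label: fentanyl
    include: [FENTANYL]
    exclude: [REMIFENTANIL]
  - label: oxycodone
    include: [OXYCODONE]
    exclude: []
  - label: codeine
    include: [CODEINE]
    exclude: [DIHYDROCODEINE]
  - label: dihydrocodeine
    include: [DIHYDROCODEINE]
    exclude: []
  - label: hydromorphone
    include: [HYDROMORPHONE]
    exclude: []
  - label: methadone
    include: [METHADONE]
    exclude: []
  - label: tapentadol
    include: [TAPENTADOL]
    exclude: []
  - label: pethidine
    include: [PETHIDINE, MEPERIDINE]
    exclude: []
  - label: loperamide
    include: [LOPERAMIDE]
    exclude: []
  - label: remifentanil
    include: [REMIFENTANIL]
    exclude: []
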