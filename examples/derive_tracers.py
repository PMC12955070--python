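"""Derive tracer diagnoses from a small Alpha-ID-SE-style terminology.

A tracer diagnosis is an ICD-10-GM code whose every diagnostic term in the
terminology carries an Orphacode — the code exclusively encodes rare
diseases, so its presence in claims data marks a rare-disease case even
when no Orphacode was documented.
"""

import io

from rddq import check_link, derive_tracers, orpha_candidates, parse_alpha_id_se

TERMINOLOGY = """\
1|I128560|Q87.5|||2097|Grant syndrome
1|I128737|Q87.5|||1824|Lowry-Wood syndrome
1|I200001|F84.2|||778|Rett syndrome
1|I200002|F84.2|||3095|Atypical Rett syndrome
1|I200003|G71.2|||53698|Congenital myopathy
1|I200004|E84.0|||586|Cystic fibrosis, pulmonary
1|I200005|E84.0||||Cystic fibrosis, unspecified term
"""

term = parse_alpha_id_se(io.StringIO(TERMINOLOGY))
tracers = derive_tracers(term)

print(f"terminology: {len(term)} diagnostic terms")
print(f"tracer codes: {sorted(tracers.codes)}")
# E84.0 is absent: one of its terms lacks an Orphacode, so the code does
# not *exclusively* encode annotated rare diseases.

print("candidates for F84.2:", sorted(orpha_candidates(term, "F84.2")))
# Two candidates (Rett / atypical Rett): an F84.2 diagnosis without an
# Orphacode leaves the rare disease ambiguous.

print("Q87.5 + Orpha:2097 ->", check_link(term, "Q87.5", 2097))
print("G71.2 + Orpha:777  ->", check_link(term, "G71.2", 777))
# The second pair appears nowhere in the terminology: an implausible link.
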