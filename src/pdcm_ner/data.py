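"""Small reference inputs shipped with the toolkit.

``ALK_ABSTRACT`` is a two-sentence excerpt from a published lung-cancer
abstract, used throughout the documentation and tests as the canonical
worked example for character-offset bookkeeping: the gene symbol "ALK"
occurs four times, so recovering *which* mention was tagged requires exact
offsets (first mention at 48..51, the parenthesised second mention at
323..326; the second sentence starts at character 182).
"""

from __future__ import annotations

ALK_ABSTRACT = (
    "Oncogenic fusion of anaplastic lymphoma kinase (ALK) with echinoderm "
    "microtubule associated protein like 4 protein or other partner genes occurs "
    "in 3% to 6% of lung adenocarcinomas. Although fluorescence in situ "
    "hybridization (FISH) is the accepted standard for detecting anaplastic "
    "lymphoma receptor tyrosine kinase gene (ALK) gene rearrangement that gives "
    "rise to new fusion genes, not all ALK FISH-positive patients respond to ALK "
    "inhibitor therapies."
)

#: Table 3-style token-classification example sentence (11 whitespace tokens).
EWING_SENTENCE = "Ewing sarcoma is a tumour of the bone and soft tissue"
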