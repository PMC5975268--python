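"""Bundled example gene orders.

The Psocoptera case study compares the mitochondrial gene order of
*Prionoglaris stygia* — the ancestral Pancrustacea arrangement — with the
rearranged order shared by the Trogiomorpha species *Lepidopsocidae sp.*
and *Dorypteryx domestica* (38 markers: 37 genes plus the control region
``CR``).  The bundled file is a SYNTHETIC reconstruction, not the
annotated GenBank records: the target order is derived as the unique
circular order at TDRL distance one from the ancestral order whose
maximal conserved segments and intergenic-framing adjacencies
(trnQ–nad2, cob–nad1) match the published description of the pair.
"""

from __future__ import annotations

from importlib import resources

from .orders import CircularGeneOrder, parse_gene_order_text

#: conserved segments reported for the case-study pair, in source order
PSOCOPTERA_CONSERVED_SEGMENTS = (
    ("trnC", "trnY", "cox1", "trnL2"),
    ("trnK", "trnD", "atp8", "atp6", "cox3"),
    ("trnG", "nad3", "trnA"),
    ("trnS1", "trnE"),
    ("trnF", "nad5", "trnH", "nad4", "nad4l", "trnT", "trnP", "nad6", "cob"),
    ("nad1", "trnL1", "rrnL", "trnV", "rrnS", "CR"),
)


def psocoptera_pair() -> tuple:
    """``(ancestral, rearranged)`` circular orders of the case study.

    Both are synthetic reconstructions (see module docstring).
    """
    text = (
        resources.files("tdrlkit")
        .joinpath("data/psocoptera_synthetic.fa")
        .read_text()
    )
    records = parse_gene_order_text(text, origin="psocoptera_synthetic.fa")
    assert len(records) == 2
    return records[0][1].circular(), records[1][1].circular()


def toy_pair() -> tuple:
    """The eight-gene worked example: identity order vs (1 2 4 6 3 5 7 8)."""
    return (
        CircularGeneOrder(range(1, 9)),
        CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8)),
    )
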