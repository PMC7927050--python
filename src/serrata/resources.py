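"""Bundled data files: default signature catalogs and the ID83 bin table."""

from __future__ import annotations

from importlib import resources

from .formats_io import read_signature_catalog
from .types import SignatureCatalog


def _data_path(name: str):
    return resources.files("serrata.data").joinpath(name)


def load_sbs_catalog() -> SignatureCatalog:
    with resources.as_file(_data_path("sbs96_catalog.tsv")) as p:
        return read_signature_catalog(p, scheme="SBS96")


def load_id_catalog() -> SignatureCatalog:
    with resources.as_file(_data_path("id83_catalog.tsv")) as p:
        return read_signature_catalog(p, scheme="ID")


def load_id83_bin_table() -> list[tuple[str, str]]:
    text = _data_path("id83_bins.tsv").read_text()
    lines = text.splitlines()[1:]
    return [tuple(line.split("\t", 1)) for line in lines if line]
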