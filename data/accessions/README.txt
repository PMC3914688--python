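Place the deposited dipluran mitogenome GenBank flatfiles here to enable
the accession-based acceptance tests (whole-genome length/AT%/skews and
the A+T-rich region span):

    JN990598.gb   Octostigma sinensis
    JN990599.gb   Parajapyx emeryanus
    JN990600.gb   Occasjapyx japonicus
    JN990601.gb   Lepidocampa weberi (circular contig)

One-time download, e.g.:

    for acc in JN990598 JN990599 JN990600 JN990601; do
      curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=gb&retmode=text" > ${acc}.gb
    done

The records are not redistributed with the package.
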