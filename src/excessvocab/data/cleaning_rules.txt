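# Example cleaning rules: action <TAB> pattern <TAB> description
# strip-match removes the matched span; drop-document removes the record
# (matched against the title when available). Rules apply in file order.
# This inventory is illustrative, not exhaustive — real corpora need a
# rule set curated against their own contamination.
strip-match	How to cite this article:.*$	citation footer
strip-match	This article is protected by copyright\..*$	copyright notice
strip-match	(Copyright|©)\s*(\(c\))?\s*\d{4}.*$	copyright line
strip-match	Communicated by:?\s+[^.]*\.	editor attribution
strip-match	\(ABSTRACT TRUNCATED AT \d+ WORDS\)	truncation marker
strip-match	Supplementary (material|information) is available.*$	supplement pointer
strip-match	Video Abstract Available\.?	video abstract flag
strip-match	Electronic supplementary material.*$	ESM pointer
drop-document	^(Erratum|Corrigendum|Correction|Retraction)\b	erratum/correction/retraction notice
drop-document	^Author Correction\b	author correction notice
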