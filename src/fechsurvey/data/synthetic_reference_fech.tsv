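his_pos	core_start	core_end	sequence
263	63	423	PWPHDYFHFTARFDWDNLRFYVDDHWFPFEPGIMKSFEDTWALRRGNYRLFRFNPVSWQWFDSPTIVNIFNWHWWSYEPTRRKEKQGNYMNKVPTGRMHLLQKFAFFSSWLPYMYLPMESNNAMLEVLIHKGAWGYYVINRGWIHPELTGYLVGKIDSDQKNSAIFVWAQDMDIEADGFYRIPEMYWKWPMNTHMQLDPPHDFLVWYQHEIPKYSSHLGRGTLFIYQLRVTMPVFYDSMFVSGGQGTWRWIGWLRGKWPYVNHTGKRWVYGFSVDLQSNAYRSHILVQWWAVRHSTQQYDTVDGPHGRNDMDTWNHTYTPYVYEKHPTFHMNWRMRNLKGHYWKKMKIFERAKDMGWHPRMLRFTWWSKDNTYQSSNLVQHVAYMFDDVSGMYHEHIEATFNGQMPLMWRAPVIETYVIELLHGSWPLNEGVTTEGARFVKNTVNGHHERYLY
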