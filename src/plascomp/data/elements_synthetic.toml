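# Synthetic stand-in descriptors for three Tn3-family transposable
# elements (Tn4656-like, Tn5053-like, Tn5563-like). IR lengths (39/25/38 bp)
# and the 5-bp target-site duplication match the published geometry of these
# families; the IR and transposase sequences themselves are SYNTHETIC,
# generated for demonstrations and tests, not the biological sequences.

["Tn4656-like"]
ir = "ATCATGTAAAGATAACTGTCACGTTTTACGGATGAGGAA"
tsd_len = 5
["Tn4656-like".proteins]
tnpA = "MATVNVSSLAAKFIECVMQEATFELKGKFNKLKFRPQIECMRGAQKDLTKKRVDAQLRDKQNEMIFQSLIFGGLATSVDSSRQHDIRLNQWGWIHIWWGINDWNEKDKGECKQMLSGKMGILDWKPRPVYSDSSQNPVWYSNYQPDCRGWMWKQAVHCHHDMIISAPPGAAQNNWDAPPRSMHSCADVQGARNCKTPLQFPMFDGCCEKQVYHTGVPGMFLSCPPEMPSWMALHMYNMLPAPCWIGGPWRFFPCWCDFGISFNAAMASTMPFVHASGDPF"
tnpR = "MRSPDALEVRDGGERPGIGVFTKNDPYVRYWASNMMWTGSCPFWVVDLFRIPKTQNCTQDHWCSPHRCGYGYKHKPDYTKWQQVTATLDCRQVCSHMINSWDSTHQGETPKWWVGRKIAPCTQECQPTEVYYEDVYHMKYAEFWRYDQSE"

["Tn5053-like"]
ir = "CTGTCGAGAGAGAGAAAACCATGGG"
tsd_len = 5
["Tn5053-like".proteins]
tnpA = "MVRQYSCLLLHSMHAEMYPRACACEGWPCKCHGKFIWVNNIEFMWSTNYPTCRCKQHHCPETQNSCKITRVDWAVLGSNVRLKKHKMMMDKEMQHGFRPCSWWFASVQCTWTDCMIYNMEPQAFEILTVVCINLARSVQVEMEIQCTGIAPFSGYYRWLEKFPAHTATWWYEPSDNEPAAPVCCHWNNVHQEPPDGFMQAVTMRMWDPGNVSNQACCDQCRLRMWFSMSHYNTKGYWVFLPNNRWPPNFGKSLKEKRRFIALVGHSVSWVQWEKHSSENP"
tnpR = "MFLDFKPKAWTSSYFTEICDYIHMGDTAIWWAYILDVPFVMNPYIESFDLNTKDGQGPWWHRPRVHAYKDETGHCPSLCWVQPGLAVCEVWKRKWMFQYKIHFTWDERQRNMDFNDFGWVVIHDHSVYKCMVYIRMIFGFSNRHFLNGGK"

["Tn5563-like"]
ir = "CTTGAGGAATCCTTACTTGACTCAACTTGCGGCTTAGA"
tsd_len = 5
["Tn5563-like".proteins]
tnpA = "MRGMVADRLPYKPESRMSFRHRDMVIWWCQIFTTTMESDSTYPGMGVCQRIQPMCITSAFGGQIKIHRIFWSMYKWYTEMVVTFGNYYAVVVCVKCDLRLQWLGYPDWHLYDGPCRDHVLIKMDDYVHKLHHYNCVHLGPRYSSLALSADQYSCFEQMHTRKCALNEHTENRCQAKDFSHDAPRQVTGGECMYLYSIIYVMWGGEEWPQKDNMPEFWDASHPYFWGRSNWELDCKHHARDRKGVQCDFRKDRWRIKAYKYVNPKEEYYCQINDAYQWQWW"
tnpR = "MVQMQGFQSGFIFMKDFYMKKYEKKPVIQISVEHNVVETVQQWESSGKAIGMDIEPTPGMHIVPSIAERIMHDVQICLGHFWACVMPANTCTFILYSFKGMNVTAIYCCLTNGHDCDSRTSTLGIVEEDPIRRLRVVSCMLKTDYNPYQA"
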