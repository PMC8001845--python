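;chromophore_columns=62,63,64
>AAU06846.1
QMWPMKWWHRWWFCAHKKEPYFAIFMCAGVPHAYTTWHHTHVGMPNKAPAKAFQDNVLGALQYGANVIPDFPYAPDFAYSDHTCYWGPQIMLEQNTDKKNQDYFRKQEKAHSSGWVMTACCKEDLGQCLIIIRVNWQQRKAHHFRTFVVNCNYDCRDHWWWRVACDVMLGAEHGYTKMVCGPPTDIIMVLAAIAIMSVCGRTHELWDFKYNGDMTCHQPASCYCEVQMYF
>ACH89428.1
QMWPCKWWHRWWFCAHKKQPGFAIFMCVGVPWAYTTWLQTHVGMPQKAPAKAFQDHVLGAEQYGENVITDFPYAPDFAYFDHTCYWYPQIMKEQNTDKKIWDYFRKQEKAHSSGSVMNRCCKEDLGAKLIIIRVNTQQRKAHHFRKFVVNCNYDCWDMPWWWVAYDVMLTAEHGYTKMVCGHPTDIDCVIAAIAIMSVQGRTHELWDFKYNGDMTCPQPASCYCEVWMYF
>AAU06849.1
QMWPCKWWHRWWFCAHKKEPYFAIFMCAGVPHAYTTWHHTHVGMPNKAPNKAFGDNVLGALQYGANVIPDFPYAPDFAYSDHTCYWGPQIMLEQNTDKKSWDYFRFQEKAHSIGWVMTACCKEDLGACLIIIRVNWVQRKAHHFETFVVNWNYDCRDHKWWRVAYDVMLGAEHKYTKMVCGPPTDIEMVLAAIAIMSVCGRTEELWDFKYNGDMTCPQPASCYCEVQMYD
>ACH89426.1
QMWPCKWWHRWWFCAHKKEPYFAIFMCRGVPHAYTTWHHTHVGMPNKAPAKAFQDNVLGDLQYGANVIPDFPYAPDFAYSDHTCYWGPQIMLEQNTDKKNWDYFRKQEKAHSSGWVMTACCKEDLGACLIYIRVNWQQRKAQHFRTFVVNCNYDCRDHPWWRVAYDVMLGAEHGYTKMVCGPPTDIIMVLAAGAIMSVCGRTHELWDFKYNGDMTCPQPASCYCEVQMYF
>AAS18271.1
QMRPIKWWMRWWFCAHKKEPYFAIFMCAGVPGAYTTWSHTHTGMPNKAPAKAYQFNVLGAYQYGLNFIPDFWYGPDFAYSRHTFYEGPQIMLEQNTDKKNWDYLRKQEKAHLSGWVMTAYCKEDLGPQLIIIRVNWQQRKAHHFRTAVVNCNYDCRDWIWWRVAYNVDLEAERSATKMVCGPPTCITKVLMAIGIFSVCGRTPMLWDFKYNGDMNCPQPASCYCESQMYM
>ACH89429.1
QMWMKKWWHRWWFVAHKYTPYFMTFMCSGCSKAYTTWHHTHRVMGHKAPAKAFQWKVSGVRDYGANVIPDFSVTPDFAQSDHTCYPGPLIMEWQNTDKNFWIYGRKQEKAHSSGKVMFASHKEDLIWCLIIGIVNWQPRKKHHFRTQVVNQNYDLRDHPWWEVQYQVNLHLEHMYTKDWCGPPTDWIMLRFAIWIFSPHGRVAELWDFKIFRDMTCPQPAFTYYEVQFVF
>AAN05449.1
QMWMKKWWHRWWFYAHKYTPYFMTFMCHGCSHAYTTWHHTHVVMPIKAPAKAFQWNVLGVLDYGANVIPDFSQAPDFAYSDHTCYPGPQIMEKQNTDKNFWDYGRKQEKAHTSGKVMIASHKEDLICCLIIGIVNWQQRQTHHFRTQVVNQNYDLRDHPWWRVQYQVNLHLEHMYTKDWCGPPTDSIMVRFAIAIFSPHGRVAELWDFHINRDMTCPQPAFCYYEVQFVF
>AAU06854.1
KMWPCKWWIRVWVMAHKKEHYFAIFMCAGVPHPYTTWTHTHVFRWFKRPAEAWQDNVLHSVQYGANQIPDNPYAPVWMYSDHTCYWGAMIMIEQHTDKKFWDYFSKQVKAHSSWQVVDAMMHYDLHACLIVIRVNWQQRKAHHFRTCTVNDNYDCRVMPWWQVAYDVMLGFEHGQTSPVRGPPTDIIAVLAADAHQDVCGRTHELSAQKYMGDETAYQPASCYCEVCMPF
>ABB17949.1
KMWPCKWWHRVWFCAHKKEPYFAIFMCAGVPHAYTTWHHTHVFRWNKAPAKAFQDNVLGSLQYGANQIPDNPYAPDWMYSDHTCYWGAMIMIEQNTDKKNWDYFRKQFKAHSSWQVVDAMCHYDLGACLIVIRVNWQQRKAHHFRTFVVNCNYDCRDMPWWQVAYDVMLGFEHGQTSMVCGPPTDIIAVLAAIAIQDVCGRTHELWSQKYMGDETCYQPASCYCEVQMPF
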