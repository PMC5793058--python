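>pseudo_reference
WDDFFQFHHFILQFNSNANCVHSVVWEINEIPWGKKFPTSGTNVCVGFTREQHELIMACS
KRVPNTHMYMRGCYLSRYPQSEGQHLWSHLIWMVGMRSNRRYQKQPVQTPMSFLIGHSTS
MESIVAYSFQSCFRMDKKVWYYSTSCIFEPPQMMEKMKNIHVYFCGMDFVEKWDFFNYMN
IIAISVHHTVQHYCPTRVSTAYVMADHIGKCFTAYITMQVHRRTWSLGDRECKGSDDQRG
YVSALCQVEKWFQCNDRMMWKSNYAPPHHYYTCMPLYVKVHYPWLPLNQLERAAPCCTPE
QWKLEQHNDFSLWEQFSQGDCLHPWQILQNHTRGNEESCHCYMDTWIRRLHYYPTMHGSV
WWVNFNGGKASWQDTFHWMQCQLANGYRKSFNLAPIVHFSKMCLVKHIYFCFYFWPKSHQ
FCTHQCRYASKWKYDFPLNNESHYYHRKEIGHVKMRYDCDDSNNMNTPGIQAQYRRVCHP
STSYIMAEVCDMDIFGADVRENAWPAHGYIHRWDEWVDHLNQFNHRHWFATYHILPKLLT
PGSFQFYCRLWKGMNFAVWPELCQSKVVCCWDSTRMWWKTCYMTYNKHENLGTTYIPWEP
AFQKRLGFVNQMGVTIIMQGMFAISVLLKHKHIVHNGLDHIRLRGCWLMALVSVFQERED
IKFCYFEFQVQVCANFDTNEPPETIIWIYWQIRHKVFCDHRSDWKHDYNVERHYPSYCVT
GYTVDCVPVILVFDFEWLLAKTSSCGCKIFAEYDEPHCGMRHSRPCSWWESRGIDVPIFS
PVMDLQDIYSAKDYRWDKWCHFWKFPKPVSTTEACGTTVHEAPQQKKQPPWNAEEECGKA
NPLYPWMNQWQFWSACGIYTTGGMMIGRNQHICRNCCMSNMMINKTTLYHISNYSCWEDY
RDDQSRCGWFRYYFVPVHKPVFWMWYNRWAMLPGQGTLRHICHPPCNMYYPHMPFRFLQH
AAVNNRGHCDPFAMLVYPYPRFFIMACMSAFMSNEQGWAYQGNFYNQYCFRVHKWDMNSV
MQCSNQADIVWDQIAYMRIEYDMAYRCLTNHEIGREWMQTPNGTAI
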